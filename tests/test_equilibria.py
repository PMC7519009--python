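"""Uniform steady states, Jury stability and the guaranteed-structure region."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ideveg import (
    ModelParams,
    dbar,
    homogeneous_jacobian,
    homogeneous_stability,
    jury_C_thresholds,
    rainfall_stability_bound,
    stable_region_params,
    steady_states,
    upper_vegetated,
)


def map_residual(state, params):
    """Fixed-point residual of the no-dispersal growth map at (u, w)."""
    u, w = state.u, state.w
    ru = params.C * (u * u * w - params.B * u)
    rw = params.D * (params.A - u * u * w - w)
    return max(abs(ru), abs(rw))


class TestSteadyStates:
    def test_closed_forms(self):
        desert, upper, lower = steady_states(2.5, 1.0)
        assert (desert.u, desert.w) == (0.0, 2.5)
        assert (upper.u, upper.w) == pytest.approx((2.0, 0.5))
        assert (lower.u, lower.w) == pytest.approx((0.5, 2.0))

    def test_degenerate_at_existence_bound(self):
        _, upper, lower = steady_states(2.0, 1.0)
        assert upper.exists and lower.exists
        assert (upper.u, upper.w) == pytest.approx((1.0, 1.0))
        assert (lower.u, lower.w) == pytest.approx((1.0, 1.0))

    def test_only_desert_below_bound(self):
        desert, upper, lower = steady_states(1.0, 1.0)
        assert desert.exists and not upper.exists and not lower.exists
        with pytest.raises(ValueError):
            upper_vegetated(1.0, 1.0)

    @given(A=st.floats(0.5, 5.0), B=st.floats(0.1, 1.9))
    @settings(deadline=None, max_examples=60)
    def test_all_states_are_fixed_points(self, A, B):
        params = ModelParams(A=A, B=B, C=0.07, D=0.21)
        for state in steady_states(A, B):
            if state.exists:
                assert map_residual(state, params) < 1e-12

    def test_independent_of_step_coefficients(self):
        a = steady_states(2.5, 1.0)
        b = steady_states(2.5, 1.0)  # states never see C, D or kernel widths
        for sa, sb in zip(a, b):
            assert (sa.u, sa.w) == (sb.u, sb.w)


class TestHomogeneousStability:
    def test_desert_jacobian_is_diagonal(self):
        params = ModelParams(A=2.0, B=0.45, C=0.1, D=0.1)
        J = homogeneous_jacobian(steady_states(2.0, 0.45)[0], params)
        np.testing.assert_allclose(J, np.diag([1 - 0.45 * 0.1, 1 - 0.1]))
        assert np.linalg.eigvals(J) == pytest.approx([0.955, 0.9])

    def test_desert_classification_bands(self):
        desert = steady_states(2.0, 0.45)[0]
        mono = ModelParams(A=2.0, B=0.45, C=0.1, D=0.1)
        assert homogeneous_stability(desert, mono).classification == "stable_monotone"
        osc = ModelParams(A=2.0, B=0.45, C=0.1, D=1.5)
        assert homogeneous_stability(desert, osc).classification == "stable_oscillatory"
        unst = ModelParams(A=2.0, B=0.45, C=0.1, D=2.5)
        assert homogeneous_stability(desert, unst).classification == "unstable"

    @given(
        A=st.floats(0.5, 4.0), B=st.floats(0.1, 1.9),
        ell=st.floats(0.05, 0.95), ell1=st.floats(0.05, 0.95),
        m=st.floats(2.1, 10.0),
    )
    @settings(deadline=None, max_examples=60)
    def test_lower_vegetated_always_unstable(self, A, B, ell, ell1, m):
        if A <= 2 * B * 1.0001:
            return
        params = ModelParams.from_stable_region(A, B, ell=ell, ell1=ell1, m=m)
        lower = steady_states(A, B)[2]
        rep = homogeneous_stability(lower, params)
        assert rep.classification == "unstable"
        # eigenvalue check agrees with the Jury margin
        eig = np.abs(np.linalg.eigvals(homogeneous_jacobian(lower, params)))
        assert eig.max() > 1.0

    def test_upper_vegetated_jury_margin_positive(self):
        params = ModelParams(A=2.5, B=1.0, C=0.1, D=0.1)
        upper = steady_states(2.5, 1.0)[1]
        rep = homogeneous_stability(upper, params)
        assert rep.stable
        eig = np.abs(np.linalg.eigvals(homogeneous_jacobian(upper, params)))
        assert eig.max() < 1.0


class TestDbar:
    def test_reference_value(self):
        assert dbar(2.5, 1.0) == pytest.approx(0.4, rel=1e-12)

    def test_large_rainfall_limit(self):
        assert dbar(1e6, 1.0) < 1e-5  # Dbar -> 0+ as A -> infinity

    def test_continuity_at_existence_bound(self):
        # approaches the A = 2B value 1 from below (square-root rate)
        vals = [dbar(2.0 * (1.0 + eps), 1.0) for eps in (1e-4, 1e-6, 1e-8)]
        assert all(np.diff(vals) > 0)
        assert vals[-1] == pytest.approx(1.0, abs=1e-3)
        assert dbar(2.0, 1.0) == pytest.approx(1.0)

    def test_always_in_unit_band(self):
        for A in np.linspace(0.91, 6.0, 30):
            assert 0.0 < dbar(A, 0.45) < 2.0


class TestStableRegion:
    def test_reference_values(self):
        C, D = stable_region_params(2.5, 1.0, 0.5, 0.5, 5.0)
        assert D == pytest.approx(0.2, rel=1e-12)
        assert C == pytest.approx(0.2 / 4.8, rel=1e-12)

    def test_small_ell1_gives_small_C(self):
        C1, _ = stable_region_params(2.5, 1.0, 0.5, 1e-6, 5.0)
        assert C1 < 1e-5

    @given(
        A=st.floats(1.0, 4.0), B=st.floats(0.1, 1.5),
        ell=st.floats(0.05, 0.95), ell1=st.floats(0.05, 0.95),
        m=st.floats(2.1, 10.0),
    )
    @settings(deadline=None, max_examples=60)
    def test_structure_preserved_or_flagged(self, A, B, ell, ell1, m):
        """The region formula preserves the state structure, except in rare
        corner configurations that the constructor flags with a warning."""
        import warnings as _w

        if A <= 2 * B * 1.0001:
            return
        with _w.catch_warnings(record=True) as caught:
            _w.simplefilter("always")
            params = ModelParams.from_stable_region(A, B, ell=ell, ell1=ell1, m=m)
        flagged = any("NOT preserved" in str(c.message) for c in caught)
        desert, upper, lower = steady_states(A, B)
        assert homogeneous_stability(desert, params).stable
        assert not homogeneous_stability(lower, params).stable
        if not flagged:
            assert homogeneous_stability(upper, params).stable
        else:
            assert not homogeneous_stability(upper, params).stable

    def test_constraint_violations_rejected(self):
        with pytest.raises(ValueError):
            stable_region_params(2.5, 1.0, 1.5, 0.5, 5.0)
        with pytest.raises(ValueError):
            stable_region_params(2.5, 1.0, 0.5, 0.5, 1.5)


class TestJuryThresholds:
    @pytest.mark.parametrize("A,B,D", [
        (2.5, 1.0, 0.1), (2.5, 1.0, 0.3), (1.0, 0.45, 0.35),
        (1.2, 0.45, 0.7), (3.0, 1.2, 0.45), (1.0, 0.45, 0.9),
    ])
    def test_interval_brackets_stability(self, A, B, D):
        """Inside the interval the upper state is stable (and desert
        monotone); 1% outside at least one condition fails."""
        thr = jury_C_thresholds(A, B, D)
        assert not thr.empty
        upper = steady_states(A, B)[1]
        desert = steady_states(A, B)[0]
        for C in np.linspace(thr.c_lo, thr.c_hi, 9)[1:-1]:
            if C <= 0:
                continue
            params = ModelParams(A=A, B=B, C=C, D=D)
            assert homogeneous_stability(upper, params).stable
            assert homogeneous_stability(desert, params).classification == \
                "stable_monotone"
        for C in (thr.c_hi * 1.01,):
            params = ModelParams(A=A, B=B, C=C, D=D)
            ok_upper = homogeneous_stability(upper, params).stable
            ok_desert = (homogeneous_stability(desert, params).classification
                         == "stable_monotone")
            assert not (ok_upper and ok_desert)

    def test_printed_thresholds_agree_with_primitive(self):
        import warnings
        for A, B, D in [(2.5, 1.0, 0.1), (1.0, 0.45, 0.6), (3.0, 1.2, 0.45)]:
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                jury_C_thresholds(A, B, D)  # no discrepancy warning raised

    def test_interval_empty_for_large_D(self):
        assert jury_C_thresholds(2.5, 1.0, 1.0).empty

    def test_stable_region_inside_interval(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            B = rng.uniform(0.1, 1.5)
            A = rng.uniform(2.05 * B, 4.0)
            ell, ell1 = rng.uniform(0.05, 0.95, 2)
            m = rng.uniform(2.1, 10.0)
            C, D = stable_region_params(A, B, ell, ell1, m)
            thr = jury_C_thresholds(A, B, D)
            assert thr.c_lo < C < thr.c_hi


class TestRainfallBound:
    def test_reference_value(self):
        expected = np.sqrt(min(0.81 / 0.19, 0.45 * 1.045**2 / 0.1))
        assert rainfall_stability_bound(0.45, 0.1) == pytest.approx(expected,
                                                                    rel=1e-12)
        assert rainfall_stability_bound(0.45, 0.1) == pytest.approx(2.0648, abs=1e-4)

    def test_diverges_in_continuous_limit(self):
        assert rainfall_stability_bound(0.45, 1e-8) > 1e3

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rainfall_stability_bound(0.45, 0.6)
        with pytest.raises(ValueError):
            rainfall_stability_bound(2.5, 0.1)

    def test_structure_holds_below_bound(self):
        """C = D = T with A below the bound preserves the state structure."""
        for B, T in [(0.45, 0.1), (0.3, 0.2), (1.0, 0.05)]:
            a_plus = rainfall_stability_bound(B, T)
            for A in np.linspace(2.0 * B * 1.001, a_plus * 0.999, 8):
                params = ModelParams(A=A, B=B, C=T, D=T, T=T)
                desert, upper, lower = steady_states(A, B)
                assert homogeneous_stability(desert, params).stable
                assert homogeneous_stability(upper, params).stable
                assert not homogeneous_stability(lower, params).stable
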