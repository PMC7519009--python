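"""Critical rainfall A_max for pattern onset, by bisection over ensembles.

For rainfall A just above the vegetated-existence bound A_min = 2B the
near-equilibrium simulations develop persistent spatial patterns; above a
critical level A_max they relax back to uniform vegetation.  ``find_amax``
locates that level per stochastic replicate by bisection on A (each run
classified patterned/uniform by the amplitude criterion) and averages the
replicates.  ``amax_experiment`` sweeps kernel widths and families,
reproducing the standard designs:

* ``simultaneous`` -- both kernels widen together; for Laplace kernels the
  water rate is a2 = 0.1 a (one tenth of the plant rate, i.e. a tenfold
  wider water kernel), mimicking the large water diffusion of the PDE.
* ``plant_only``   -- water kernel fixed (Laplace, a2 = 0.1), plant kernel
  width/shape varies.  Wider plant dispersal inhibits patterning.
* ``water_only``   -- plant kernel fixed (Laplace, a = 1), water kernel
  width varies.  Wider water redistribution promotes patterning.
* ``sigma_B_plane`` -- A_max over a (sigma_phi, B) grid (Laplace kernels,
  a2 = 0.1 fixed), probing a dispersal-distance/mortality trade-off.

All designs use the stable-region step coefficients (ell = ell1 = 0.5,
m = 5) so the uniform-state structure is guaranteed at every rainfall
level probed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .equilibria import ModelParams
from .kernels import KernelSpec, width_from_std
from .simulator import Grid, run

__all__ = ["ThresholdResult", "BracketError", "find_amax", "amax_experiment"]


class BracketError(RuntimeError):
    """The rainfall bracket does not straddle the patterned/uniform change."""


@dataclass
class ThresholdResult:
    """Per-replicate and aggregated estimates of the rainfall threshold."""

    a_max_mean: float
    a_max_replicates: np.ndarray
    interval_width: float
    seeds: np.ndarray
    bracket: tuple[float, float]
    n_replicates: int
    meta: dict = field(default_factory=dict)

    @property
    def a_max_std(self) -> float:
        return float(np.std(self.a_max_replicates, ddof=1)) if self.n_replicates > 1 else 0.0

    @property
    def a_max_stderr(self) -> float:
        return self.a_max_std / np.sqrt(self.n_replicates)


def _default_param_factory(
    B: float, ell: float, ell1: float, m: float
) -> Callable[[float], ModelParams]:
    def factory(A: float) -> ModelParams:
        return ModelParams.from_stable_region(A, B, ell=ell, ell1=ell1, m=m)

    return factory


def find_amax(
    plant_kernel: KernelSpec,
    water_kernel: KernelSpec,
    B: float = 0.45,
    param_factory: Optional[Callable[[float], ModelParams]] = None,
    tol: float = 1e-4,
    n_replicates: int = 10,
    A_bracket: Optional[tuple[float, float]] = None,
    seed: Optional[int] = None,
    grid: Optional[Grid] = None,
    n_steps: int = 1000,
    x_sub: float = 50.0,
    rel_threshold: float = 0.05,
    window: int = 50,
    ell: float = 0.5,
    ell1: float = 0.5,
    m: float = 5.0,
    bisect_outcomes: bool = False,
    max_widen: int = 4,
) -> ThresholdResult:
    """Estimate the critical rainfall A_max below which patterns form.

    Per replicate the outcome change is bisected in A until the interval is
    shorter than ``tol`` (estimate: interval midpoint); the mean over
    replicates is reported.  Replicate seeds derive from ``seed`` via a
    splittable ``SeedSequence`` so ensembles are reproducible.

    The bracket defaults to (2B, max(3B, 2B + 1)).  If the lower endpoint
    already relaxes to uniform vegetation, no rainfall level supports
    patterns and A_max = 2B (the delta-kernel limit).  If the upper
    endpoint still patterns, the bracket is widened up to ``max_widen``
    times before a ``BracketError`` reports both endpoint outcomes.

    Runs classified exactly on the pattern criterion's boundary count as
    uniform (strict inequality), nudging marginal estimates downward.

    With ``bisect_outcomes`` the replicate ensemble is run at every probed
    A and the *majority* outcome drives a single bisection (the alternative
    reading of ensemble averaging); the per-replicate column then repeats
    the common estimate.
    """
    if param_factory is None:
        param_factory = _default_param_factory(B, ell, ell1, m)
    if A_bracket is None:
        A_bracket = (2.0 * B, max(3.0 * B, 2.0 * B + 1.0))
    lo0, hi0 = A_bracket
    if lo0 < 2.0 * B - 1e-12:
        raise ValueError("lower bracket endpoint must be >= 2B")
    if grid is None:
        grid = Grid()
    ss = np.random.SeedSequence(seed)
    child_seeds = np.array([int(s.generate_state(1)[0] % (2**31)) for s in
                            ss.spawn(n_replicates)])

    def patterned(A: float, rep_seed: int) -> bool:
        res = run(
            param_factory(A), plant_kernel, water_kernel, grid=grid,
            n_steps=n_steps, seed=int(rep_seed), x_sub=x_sub,
            rel_threshold=rel_threshold, window=window, early_stop=True,
        )
        if res.outcome == "aborted_negative":
            # near A_min strong onset can overshoot into negative water; if
            # the amplitude had already exceeded the pattern threshold, the
            # instability is unambiguous and the run counts as patterned
            if np.nanmax(res.amplitude) > rel_threshold:
                return True
            raise RuntimeError(
                f"simulation went negative before any growth at A={A}"
            )
        if res.outcome == "aborted_divergent":
            raise RuntimeError(f"simulation diverged at A={A}")
        return res.outcome == "patterned"

    def classify(A: float) -> bool:
        if bisect_outcomes:
            votes = sum(patterned(A, s) for s in child_seeds)
            return votes * 2 > n_replicates
        raise AssertionError  # per-replicate path bisects individually

    def bisect(outcome_at: Callable[[float], bool]) -> float:
        lo, hi = lo0, hi0
        if not outcome_at(lo):
            return lo  # never patterns: threshold collapses to A_min = 2B
        widened = 0
        while outcome_at(hi):
            widened += 1
            if widened > max_widen:
                raise BracketError(
                    f"patterned at both endpoints ({lo0}, {hi}) after "
                    f"{max_widen} widenings"
                )
            hi = lo0 + 2.0 * (hi - lo0)
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if outcome_at(mid):
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    if bisect_outcomes:
        est = bisect(classify)
        reps = np.full(n_replicates, est)
    else:
        reps = np.array([
            bisect(lambda A, s=s: patterned(A, s)) for s in child_seeds
        ])
    return ThresholdResult(
        a_max_mean=float(reps.mean()),
        a_max_replicates=reps,
        interval_width=tol,
        seeds=child_seeds,
        bracket=(lo0, hi0),
        n_replicates=n_replicates,
        meta={
            "B": B, "ell": ell, "ell1": ell1, "m": m,
            "plant_kernel": plant_kernel.to_dict(),
            "water_kernel": water_kernel.to_dict(),
        },
    )


DESIGNS = ("simultaneous", "plant_only", "water_only", "sigma_B_plane")

# reduced default grids (subsampling the printed ones); full grids via flags
DEFAULT_SIGMA_PLANT = (0.1, 0.25, 0.5, 1.0, 2.0)
DEFAULT_SIGMA_WATER = (1.0, 2.0, 5.0, 10.0, 20.0)
FULL_SIGMA_PLANT = tuple(np.round(np.arange(0.05, 2.001, 0.05), 3))
FULL_SIGMA_WATER = tuple(float(s) for s in range(1, 21))


def _water_for_simultaneous(
    family: str, sigma_plant: float, water_width_mode: str, b: Optional[float]
) -> KernelSpec:
    if water_width_mode == "rate_scaled":
        if family != "laplace":
            raise ValueError(
                "rate_scaled water width (a2 = 0.1 a) is defined for the "
                "Laplace family only; use water_width_mode='matched_sigma'"
            )
        return KernelSpec("laplace", a=0.1 * np.sqrt(2.0) / sigma_plant)
    if water_width_mode == "matched_sigma":
        return width_from_std(family, 10.0 * sigma_plant, b=b)
    raise ValueError(f"unknown water_width_mode {water_width_mode!r}")


def amax_experiment(
    design: str,
    families: Sequence[str] = ("laplace",),
    sigma_grid: Optional[Sequence[float]] = None,
    B_grid: Optional[Sequence[float]] = None,
    B: float = 0.45,
    ell: float = 0.5,
    ell1: float = 0.5,
    m: float = 5.0,
    power_law_b: float = 4.0,
    water_width_mode: str = "rate_scaled",
    seed: Optional[int] = None,
    full: bool = False,
    **find_kwargs,
) -> pd.DataFrame:
    """Sweep A_max over kernel widths/families for one experiment design.

    Returns a tidy frame with one row per grid point (design coordinates,
    mean A_max, replicate spread, seeds).  Failures at individual grid
    points are recorded in the ``error`` column and the sweep continues.

    For the ``simultaneous`` design the water kernel width follows the
    plant kernel either by the rate rule a2 = 0.1 a (Laplace only,
    ``rate_scaled``) or by a tenfold standard deviation
    (``matched_sigma``, any family); the two coincide for Laplace kernels.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; choose from {DESIGNS}")
    rows = []
    master = np.random.SeedSequence(seed)

    def one(make_kernels, coord, Bval):
        sub = master.spawn(1)[0]
        row = dict(coord)
        row.update(B=Bval, design=design)
        try:
            plant, water = make_kernels()
            res = find_amax(
                plant, water, B=Bval, ell=ell, ell1=ell1, m=m,
                seed=int(sub.generate_state(1)[0] % (2**31)), **find_kwargs,
            )
            row.update(
                a_max=res.a_max_mean,
                a_max_std=res.a_max_std,
                a_max_stderr=res.a_max_stderr,
                interval_width=res.interval_width,
                n_replicates=res.n_replicates,
                seeds=";".join(str(s) for s in res.seeds),
                error="",
            )
        except Exception as exc:  # per-point failure: record, continue
            row.update(
                a_max=np.nan, a_max_std=np.nan, a_max_stderr=np.nan,
                interval_width=np.nan, n_replicates=0, seeds="",
                error=f"{type(exc).__name__}: {exc}",
            )
        rows.append(row)

    if design == "simultaneous":
        sigmas = sigma_grid if sigma_grid is not None else (
            FULL_SIGMA_PLANT if full else DEFAULT_SIGMA_PLANT)
        for fam in families:
            for s in sigmas:
                b = power_law_b if fam == "power_law" else None
                one(lambda fam=fam, s=s, b=b: (
                    width_from_std(fam, s, b=b),
                    _water_for_simultaneous(fam, s, water_width_mode, b)),
                    {"family": fam, "sigma_plant": s}, B)
    elif design == "plant_only":
        sigmas = sigma_grid if sigma_grid is not None else (
            FULL_SIGMA_PLANT if full else DEFAULT_SIGMA_PLANT)
        water = KernelSpec("laplace", a=0.1)
        for fam in families:
            for s in sigmas:
                b = power_law_b if fam == "power_law" else None
                one(lambda fam=fam, s=s, b=b: (width_from_std(fam, s, b=b), water),
                    {"family": fam, "sigma_plant": s}, B)
    elif design == "water_only":
        sigmas = sigma_grid if sigma_grid is not None else (
            FULL_SIGMA_WATER if full else DEFAULT_SIGMA_WATER)
        plant = KernelSpec("laplace", a=1.0)
        for fam in families:
            for s in sigmas:
                b = power_law_b if fam == "power_law" else None
                one(lambda fam=fam, s=s, b=b: (plant, width_from_std(fam, s, b=b)),
                    {"family": fam, "sigma_water": s}, B)
    else:  # sigma_B_plane
        sigmas = sigma_grid if sigma_grid is not None else DEFAULT_SIGMA_PLANT
        Bs = B_grid if B_grid is not None else (0.2, 0.45, 0.9)
        water = KernelSpec("laplace", a=0.1)
        for s in sigmas:
            for Bval in Bs:
                one(lambda s=s: (width_from_std("laplace", s), water),
                    {"family": "laplace", "sigma_plant": s}, Bval)
    return pd.DataFrame(rows)
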