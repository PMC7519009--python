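# Methods

## Model

The package simulates and analyses a discrete-season vegetation–water
system on a one-dimensional domain. One step advances both densities
through a growth season and a dispersal season:

    uₙ₊₁(x) = C (φ ∗ f)(x),   f(u, w) = u²w − Bu + u/C
    wₙ₊₁(x) = D (φ₁ ∗ g)(x),  g(u, w) = A − u²w − w + w/D

*u* is plant density, *w* water density; *A* is rainfall, *B* plant loss,
and *C*, *D* scale how much growth-phase change accumulates between
dispersal events. The kernels φ (seeds) and φ₁ (water) are probability
densities; φ is symmetric (isotropic seed dispersal), φ₁ may be asymmetric
with non-positive mean to represent downhill water flow on a slope. All
quantities are dimensionless, inherited from the standard
nondimensionalisation of the continuous Klausmeier model

    u_t = u²w − Bu + u_xx
    w_t = A − w − u²w + ν w_x + d w_xx ,

which the map approaches under the *season scaling*

    C = D = T,  σ²_φ = 2T,  μ_φ₁ = −νT,  σ̃²_φ₁ = 2dT

as the season length T → 0 (local truncation error O(T²)). T is the time
between dispersal events; d is water diffusion relative to seed diffusion.

### Uniform states and homogeneous stability

The spatially uniform equilibria coincide with those of the continuous
model: a desert state (0, A) and, for A ≥ 2B, a vegetated pair
(2B/(A∓s), (A∓s)/2) with s = √(A²−4B²); the pair coincides at A = 2B,
which is treated as existing-but-degenerate so that the classic
demonstration point A = 2B = 0.9 remains runnable. Stability to spatially
homogeneous perturbations is decided by the Jury conditions det(J) < 1 and
1 + det(J) − |tr(J)| > 0 on the Jacobian of the local two-variable map.
Jury margins within 1e−12 of zero are reported as `marginal` rather than
silently classified.

Two parameterisations keep the continuous-time stability structure (desert
and upper vegetated stable, lower vegetated unstable):

* the *stable-region* coefficients D = ℓ·D̄, C = ℓ₁D̄/(B(m − ℓ₁D̄)) with
  ℓ, ℓ₁ < 1, m > 2 and D̄ = 2(A² − As − 2B²)/(A² − As). The classical
  sufficiency argument for this region contains a flawed step (it involves
  A² − A√(A² + 4B²), which is negative), and the region is in fact *not*
  universally safe: in rare corners (ℓ ≲ 0.1 with ℓ₁ near 1, m near 2 and
  B large, roughly 0.1 % of broadly sampled configurations) the resulting
  C exceeds the Jury-admissible interval and the vegetated state is
  oscillatorily unstable through det(J) > 1. `stable_region_params`
  therefore verifies its output against the primitive Jury conditions and
  emits a `RuntimeWarning` when the formula fails. The slice
  ℓ = ℓ₁ = 0.5, m = 5 used by all shipped experiments is unaffected
  (checked on a dense grid).
* the season scaling C = D = T, which requires T < 1/2, B < 2 and a
  rainfall bound A < A₊(B, T) = √min{4B²/((2−T)T), B(BT+1)²/T}; A₊ → ∞ as
  T → 0, recovering the unrestricted continuous-time region.

`jury_C_thresholds` computes the admissible C-interval at fixed (A, B, D)
directly from the primitive Jury inequalities (each is linear in C) and
evaluates the closed-form thresholds C̄₁–C̄₃ only as cross-checks, warning
on disagreement instead of committing to a sign convention.

### Pattern onset

Linearising about the upper vegetated state and Fourier transforming gives
the mode-k Jacobian

    J(k) = [[C φ̂(k) α, C φ̂(k) β], [D φ̂₁(k) γ, D φ̂₁(k) δ]]

with α = (BC+1)/C, β = 4B²/(A−s)², γ = −2B and
δ = −2(A²D − ADs − A² + As + 2B²)/(D(A−s)²). On flat ground (symmetric
φ₁) J is real and mode k is unstable when a Jury condition fails. Sloped
ground makes J complex; the analysis layer detects this and raises rather
than approximating, since the flat-ground Jury argument does not apply.

With Laplace kernels under the season scaling the Jury margin reduces to a
quartic: the numerator of 1 + det(J) − tr(J) is proportional to
γ₄k⁴ + γ₂k² + γ₀ with

    γ₄ = d(q − 2B²),  γ₂ = q(1 − Bd) + 2B³d,  γ₀ = −B(q − 4B²),  q = A² − As.

The coefficients are independent of T: pattern onset in the seasonal model
is the same diffusion-driven instability as in the continuous model,
occurring exactly for d > d_c(A, B). The constant term γ₀ used here was
re-derived symbolically from J(k); a commonly quoted variant, B(A² − 4B²),
is inconsistent with the Jacobian and would displace the threshold by
~13 % at (A, B) = (1, 0.45). With the re-derived γ₀ the quartic's
sign-change locus matches the closed-form d_c to machine precision, and
both match a direct numerical scan of the margin.

`critical_diffusion` evaluates the closed form; `critical_diffusion_root`
re-derives d_c by Brent bisection on the quartic minimum −γ₂²/(4γ₄) + γ₀
over d ∈ [1, 10⁶], verifying a sign change at the bracket ends. The
default dispersion grid is 2000 log-spaced wavenumbers in [10⁻³, 10³] plus
the analytic minimiser k* = √(−γ₂/(2γ₄)) when defined, so a sharp margin
minimum cannot slip between grid points.

## Simulation

The map runs on a uniform periodic mesh of M points over [−x_max, x_max).
Kernels are sampled at the mesh offsets in DFT wrap-around order,
truncated to the domain, and renormalised so that Δx·Σφ = 1 exactly —
this makes the uniform steady states exact fixed points of the discrete
map (verified to ~4e−15 over 500 steps). A warning is raised when the
analytic tail mass outside the domain exceeds 10⁻⁶ (relevant for the
heavy-tailed power-law kernel with b = 3.1 on modest domains).
Convolutions are evaluated with the real FFT, kernels transformed once per
run; the step was validated against the O(M²) convolution sum to 10⁻¹⁰.

Initial conditions follow the near-equilibrium protocol: on an interior
subdomain [−x_sub, x_sub] each mesh point receives i.i.d. uniform noise
bounded in sup-norm by 0.1·(steady state); outside, the state is exact.
The outer buffer insulates the periodic boundary: doubling x_max at fixed
x_sub leaves the subdomain trajectory unchanged to 10⁻⁶ over the horizons
used. Negative or non-finite densities abort a run with a regime flag
(`aborted_negative` / `aborted_divergent`) — they are biologically
impossible and are not clipped.

Defaults: x_max = 200, M = 4096 (Δx ≈ 0.1, comfortably resolving the
onset wavelength ~17 and kernels down to σ ≈ 0.3), x_sub = 50,
n_steps = 1000. A run is classified *patterned* when the mean of the
amplitude series max|u−ū|/ū over the last 50-step window exceeds 0.05 and
is non-decaying (≥ 0.9× the previous window's mean); the oscillation
criterion itself is a package decision, as only the idea of an
amplitude-based classification is standard. With `early_stop` a run ends
as soon as the classification is settled (three consecutive windows above
threshold without decay, or collapse to below 10⁻⁴ of the threshold while
still decaying).

One step of the map is one full annual cycle (growth season + dispersal
season), i.e. two seasons in calendar terms.

## Critical rainfall A_max

For fixed kernels and the stable-region coefficients, patterns form for
rainfall in (2B, A_max). `find_amax` bisects A per stochastic replicate —
patterned at the low end, uniform at the high end — until the interval is
below `tol` (default 10⁻⁴), then averages replicates; replicate seeds come
from a splittable `SeedSequence`, so ensembles are reproducible from one
master seed. Design choices:

* If the lower endpoint (A = 2B) already relaxes to uniform, the threshold
  has collapsed and A_max = 2B is returned (the delta-kernel limit).
* If the upper endpoint still patterns, the bracket is widened (up to 4
  doublings) before failing with both endpoint outcomes.
* Marginal runs count as uniform (strict threshold inequality), nudging
  estimates downward deterministically.
* Near A = 2B strong onset can overshoot plant peaks until water goes
  negative; a run aborted this way *after* its amplitude exceeded the
  pattern threshold is counted as patterned (the instability is
  unambiguous), while an abort without prior growth is an error.
* Whether one should bisect per replicate and then average, or run the
  ensemble at each probed A and bisect on the majority outcome, is
  genuinely open; per-replicate bisection is the default, the ensemble
  variant is available via `bisect_outcomes=True`.
* Default replicate count is 10 (desk-scale runs); larger ensembles are a
  flag away.

`amax_experiment` sweeps kernel widths for four designs. The default σ
grids subsample the full grids (σ_φ up to 2 in steps of 0.05; σ_φ₁ from 1
to 20), which remain available via `full=True`. For the simultaneous
design the water width follows the plant kernel either by the Laplace rate
rule a₂ = 0.1a or by a tenfold standard deviation (`matched_sigma`), which
generalises the rule to non-Laplace water kernels; the two coincide for
Laplace kernels, and no canonical non-Laplace mapping is assumed.

## Continuous-model reference

`solve_pde` integrates the continuous system by method of lines:
second-order central differences for both diffusion terms, first-order
upwind differencing for the advection ν·w_x (characteristics travel toward
−x), and stiff adaptive time integration (BDF) with the Jacobian sparsity
pattern supplied. Spatial refinement was verified second-order, and the
empirically located onset threshold (bisection in d on single-mode growth)
agrees with the closed-form d_c within 5 %.

`convergence_vs_T` maps one seeded initial condition onto both models and
reports the plant-density sup-norm gap on the perturbed subdomain at a
common physical time (map time = steps × T). Consistency guarantees only
O(T²) local truncation, not a solution-convergence rate, so the check
asserts monotone error decrease along T = 0.3, 0.2, 0.1 — observed
robustly (error roughly ∝ T) at A = 1, B = 0.45, d = 20 on a 1024-point
domain of half-width 50 with horizon 10, the configuration shipped in the
tests and acceptance script. These values keep the vegetated state in the
stable regime (d < d_c) so the gap measures scheme discrepancy rather than
diverging pattern phases.

## What the synthetic conditions do and do not show

All inputs are generated: there is no field data. The randomised
near-equilibrium initial conditions probe *onset* — whether infinitesimal
spatial structure grows — under exactly the idealisations of the analysis
(periodic 1-D domain, uniform parameters, i.i.d. bounded noise). Passing
tests therefore validate the pattern-onset machinery, not ecological
realism: they say nothing about fully developed pattern selection or
stability, 2-D morphology (gaps, labyrinths, stripes), heterogeneous
terrain, or stochastic rainfall. The divergent/chaotic/period-doubling
regimes of the map outside the guaranteed region are detected only as
aborted runs and deliberately not classified.

## Numerical choices and limitations

* Power-law kernel transforms use cosine-weighted quadrature; the
  asymmetric Laplace transform uses its elementary closed form
  N[1/(a₂+ik) + 1/(a₂−a₁−ik)], cross-checked against quadrature.
* Power-law kernels require b > 3 for any standard-deviation-based
  comparison; b ∈ {3.1, 4} are the intended values, and infinite-variance
  requests raise a dedicated error.
* Sloped-ground simulation is supported mechanically (asymmetric water
  kernel solved from its first two moments), but no sloped-ground
  stability claims are made; the analysis layer rejects complex Jacobians.
* Bisection tolerances: d_c root to relative 10⁻¹²; A_max interval 10⁻⁴ by
  default (10⁻³ in the shipped ensemble experiments, where Monte-Carlo
  replicate spread of order 10⁻²–10⁻¹ dominates the bisection error).
* Near A = 2B the slowest decay rate vanishes like √(A−2B), so any
  finite-window amplitude classifier resolves the delta-kernel collapse of
  A_max only to ~10⁻³; the delta-*water* collapse is exact because the
  lower bracket endpoint itself classifies uniform.
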