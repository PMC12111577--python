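# Methods

## Model and assumptions

`mhckin` models the competition between non-enzymatic (disulfide)
polymerization and proteolytic degradation of myosin heavy chain (MHC)
during single-step heating of surimi. Three states are tracked: normalized
monomer `X`, normalized polymer `P`, and core temperature `T`. Polymerization
converts `X` to `P` at rate `k1·s(T)`, where the sigmoid gate
`s(T) = (T/T1)^d / (1+(T/T1)^d)` is the thermally denatured fraction of MHC
(only unfolded monomer aggregates). Degradation removes both `X` and `P` at
rate `k2·g(T)`, where `g(T) = exp(-(T-T_opt)²/(2β²))` is a Gaussian
protease-activity profile peaking at `T_opt`. Key assumptions:

* degradation products are not tracked — degraded mass leaves the system
  (no fragment pool in the state);
* enzymatic (TGase) cross-linking is absent, appropriate for species/
  temperature ranges where its activity is negligible;
* monomer and polymer are degraded at the same specific rate;
* heating is first-order (Newtonian), `dT/dt = α(T_max - T)`, so
  `T(t) = T_max - (T_max - T_init)·e^(-αt)` in closed form;
* amounts are normalized to the unheated sample (X(0)=1, P(0)=0), matching
  densitometry series normalized to their t = 0 reference.

The model is observed through two channels: electrophoresis with disulfide
reduction reports `X + P`, without reduction `X` alone.

### Parameters (defaults = the reference 60 °C heating condition)

| name | meaning | unit | default |
|------|---------|------|---------|
| k1 | max polymerization rate | 1/min | 0.044 |
| k2 | max degradation rate | 1/min | 0.053 |
| T1 | unfolding-sigmoid inflection | °C | 29.61 |
| d | unfolding-sigmoid steepness | — | 22.34 |
| T_opt | protease optimum | °C | 60 |
| β | protease-gate width | °C | 0.214 |
| α | heating rate | 1/min | 0.3 |
| T_max | bath temperature | °C | 60 |
| T_init | initial core temperature | °C | 0 (ice-stored samples; configurable) |

With these values the core comes within 0.5 °C of the bath at ≈ 16 min, the
unfolding gate opens (s > 0.5) at ≈ 2.3 min, and the protease gate stays
below 1% activity until ≈ 15 min — the mechanism behind the observed delay
between monomer loss and total-MHC loss.

## Numerics

* **Integration.** Temperature is evaluated from its closed form inside the
  right-hand side (exactly equivalent to integrating the third equation);
  the (X, P) subsystem is stepped with classical fixed-step RK4, default
  step 0.01 min. The system is smooth and non-stiff at these parameter
  scales; step-halving changes the solution by ~1e-12, and an optional
  convergence check (`check_convergence=True`) enforces ≤ 1e-6. Tests
  cross-validate against scipy's DOP853 at rtol 1e-11 and against
  constant-temperature closed forms. One broadcast-aware code path serves
  both scalar simulation and the batched grid search, so generator and
  fitter arithmetic are identical (noise-free self-RSS is exactly 0).
* **Gate evaluation.** The sigmoid is computed as `expit(d·ln(T/T1))` — the
  algebraically identical log-space form — to avoid overflow at large
  steepness; its value at T = 0 is defined as 0 by continuity, and negative
  temperatures are rejected rather than given a branch.
* **Onset times.** The first crossing of a channel below a stated fraction
  is bracketed on the output grid and refined by bisection (xtol 1e-10) on
  a monotone piecewise-cubic (PCHIP) interpolant, decoupling the metric
  from the output spacing; an output grid of ≤ 0.5 min reproduces the
  0.01-min result to < 1e-3 min. Never-crossing channels return `inf`.
* **Grid search.** Coarse-to-fine: each level places an even grid over the
  current box (defaults: k1, k2 ∈ [0, 0.2] step 0.01; β ∈ [0.01, 2.0] step
  ≈ 0.0995 — brackets the defaults by an order of magnitude), then the box
  shrinks by a factor 0.2 about the best point (clipped to the original
  bounds), four levels in total, giving final per-axis resolution 8e-5 for
  the rate constants and 8e-4 for β. RSS pools both channels and all
  replicates with equal weight (configurable weighting was considered and
  rejected as an unforced free parameter). Exact RSS ties break to the
  lexicographically smallest (k1, k2, β); the whole search is
  deterministic. A single-level grid is exhaustively compared against a
  brute-force loop over `residual_sum_squares` in the tests.
* **Sigmoid/heating fits.** Damped least squares
  (`scipy.optimize.least_squares`, trust-region reflective). The sigmoid
  fit multi-starts from five log-spaced steepness values (d₀ ∈ [1, 100])
  because steep sigmoids have narrow basins in `d`; the inflection start is
  taken from the observed 0.5-crossing. The heating fit fixes `T_max`,
  anchors `T_init` at the first logged point, and starts from an algebraic
  single-point inversion. Degenerate inputs (constant curves, < 3 points,
  curves not spanning 0.5, logs saturated at `T_max`) raise `FitError`.

## Synthetic data

The generators emulate the *numeric* outputs of the wet-lab workflow, not
the gels themselves: normalized band-intensity tables at sampling times
2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 30, 40, 60 min with 3 replicates
(plus the t = 0 anchor, value 1 by normalization), a denaturation curve on
a regular temperature grid, and a logged heating trace. Measurement noise
is additive Gaussian on the normalized-intensity scale (default sd 0.05 —
a plausible replicate scatter for densitometry; real replicate variance is
instrument- and gel-dependent), truncated at zero, and renormalized to the
t = 0 reference, mirroring the normalization step of the real workflow.
Every generator is a pure function of (parameters, seed) and is
bit-reproducible.

What passing tests therefore show: the estimation machinery recovers known
parameters from data with the assumed statistical structure at the design's
sampling times. What they cannot show: robustness to gel artifacts
(smearing, background, saturation), non-Gaussian or intensity-dependent
densitometry error, co-migrating fragments inflating band intensities, or
model misspecification (e.g. unequal degradation rates for monomer and
polymer). Conclusions about real gels still require real densitometry.

## Design choices

* `T_opt` is fixed, never estimated: the time courses barely constrain it
  (the gate is near-binary along the heating trajectory), and it is
  identified independently from temperature-series gel data.
* The two meanings that a bare symbol "T0" could carry are split into two
  fields: `T_opt` (degradation optimum) and `T_init` (initial core
  temperature).
* `T_max == T_init` is allowed, giving isothermal runs used by the
  closed-form validation tests.
* Estimation is grid search by design, not gradient-based or Bayesian: the
  objective is cheap in batch, the search is derivative-free, deterministic
  and trivially auditable, which is what a three-parameter problem needs.
* Problem sizes in the test and reproduction pipelines (13 sampling times ×
  2 channels, 51-point denaturation curve, 21-point heating log, 20
  recovery replicates at noise sd 0.05) match the reference experimental
  design; the recovery replicate count is the package's validation choice.

## Known limitations

* The Gaussian gate with the default β (0.214 °C) is extremely narrow;
  degradation is effectively off until the core is within ~1 °C of the
  optimum. Fits of β from sparse, noisy data show upward bias (the RSS
  surface is asymmetric around small β); the recovery harness quantifies
  this rather than hiding it.
* Only single-step heating programs are modelled; two-step schedules are an
  extension point, not a feature.
* No link from (X, P) to mechanical gel properties is provided; the model
  describes protein state, not texture.
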