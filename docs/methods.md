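# Methods

## Model

A single cohort of `N0` seedlings from one provenance is planted at year 0
and censused at harvest, year `H`. The life cycle is a ladder of `n`
discrete stages: each year an individual in stage `i` survives with
probability `s_i(θ, T_t)` and, conditional on surviving, advances to stage
`i+1` with probability `g_i` (the last stage is absorbing). Individuals
never shrink or skip stages, and the cohort does not reproduce — harvest is
the expected number of last-stage individuals at year `H`, which a
conservation reading can take as the number reaching peak reproductive
stage.

Survival responds to climate through a Gaussian norm,
`s_i = s_i,max exp(−(θ − T_t)²/(2 ω_i²))`: a provenance does best in years
matching its thermal optimum θ (constant over life), and a one-width
mismatch costs a factor `1 − e^{−1/2} ≈ 40%` of annual survival. The
maximal rates `s_i,max` and the growth probabilities `g_i` are read off an
empirical transition matrix under the assumption that it was measured at
the population's optimum: `s_i,max = stasis + growth` per column and
`g_i = growth / s_i,max`.

Climate is a linear trend `T_t = T0 + k t` for `t = 1..H` (selection starts
the year after planting; the planting-year temperature enters nothing),
optionally with independent Gaussian fluctuations of standard deviation
`σ_f` around the trend. A consequence of the 1-based indexing is that the
constant-tolerance optimal provenance is `T0 + k (H+1)/2`, not
`T0 + k H/2`. No interannual autocorrelation is modelled.

## Closed forms

For a fixed life history `a⃗` (transition ages), expected harvest is the
product of yearly Gaussian survivals, which reorganises exactly into a
single Gaussian in θ with

- width `ω_tot² = (Σ_i d_i/ω_i²)^{-1}` (stage durations `d_i` aggregated
  harmonically; constant width gives `ω_tot = ω/√H`),
- mode `T_tot = Σ_t (ω_tot²/ω_i(t)²) T_t` (the weights sum to one), and
- peak `s_tot,max = Π_i s_i,max^{d_i} · exp(T_tot²/(2ω_tot²) − Σ_t
  T_t²/(2ω_i(t)²))`, computed in log space.

Year `t` belongs to stage `i` when `a_{i−1} < t ≤ a_i` (with `a_0 = 0`,
`a_n = H`); `a_{n−1} = H` is allowed and contributes an empty final-stage
product. With stochastic growth the expectation is the sum of this closed
form over all `C(H, n−1)` life histories weighted by
`p(a⃗) = Π_i (1−g_i)^{a_i−a_{i−1}−1} g_i`. This mixture equals the
year-by-year matrix projection identically (verified to 1e−8 relative error
across the provenance grid and all warming scenarios in the test suite);
enumeration is guarded by a configurable cap (default 2×10⁶ histories)
beyond which callers fall back to the simulator.

A cohort with Gaussian variation of optima (mean `θ̄`, sd `σ_p`) convolves
two Gaussians: width `√(ω_tot² + σ_p²)`, peak scaled by
`ω_tot/√(ω_tot² + σ_p²)`. This closed form is derived here and validated
against numerical quadrature to 1e−8 relative error in the tests.

## Tolerance ontogeny and calibration

Stage widths follow `ω_i² = ω₁²(1 + b(i−1))`, `b > −1/(n−1)`; `b` may also
be given as the last/first ratio via `b = (ratio² − 1)/(n − 1)`. To compare
ontogeny scenarios at a fixed lifetime niche width, `ω₁` is calibrated so
that the cumulative tolerance over a reference life history equals a target
(presets 2, 3.5, 5 °C): `ω₁² = ω_tot² Σ_i d_i/(1 + b(i−1))`, an exact
inverse. The reference life history is the *typical* one: partial sums of
expected stage occupancies from the fundamental matrix `F = (I − U)^{-1}`
(first column), rounded up to the next integer, with ties bumped to keep
ages strictly increasing. "Round up" is our reading of rounding "to the
next integer"; it reproduces the reference two-stage case (expected
juvenile duration 2.52 → maturation age 3). The same occupancies are also
available in closed form from the vital rates, which additionally covers
absorbing last stages where `I − U` is singular.

Because the typical life history is not conditioned on surviving to
harvest, the cohort's realised (effective) lifetime tolerance differs from
the calibrated one. `effective_cumulative_tolerance` quantifies this by
fitting a quadratic to log expected harvest against θ under a constant
climate and converting the curvature to a width; survivors mature earlier
than the unconditional expectation whenever juvenile survival is the
bottleneck, so the effective tolerance is wider than the calibrated target
and the excess grows with the ontogeny contrast. The fit window (±0.5
ω_tot, 101 points) is a diagnostic choice; the mixture is not exactly
Gaussian, so the fitted width is a local description around the optimum.

## Optimisation and strategies

The best provenance is searched on a θ grid from `T0` to `T0 + 4` °C in
0.01 °C steps (widened to `T0 ± 5` °C for fluctuation runs, where cold
realisations can favour optima below `T0`). Ties break toward the cooler
provenance — the conservative translocation — and a maximum on the grid
boundary raises a warning. Strategy comparison evaluates three sources on
the same realised series: the local provenance (θ = T0), the grid-searched
best, and the quarter-rotation rule θ = `T0 + k H/4` snapped to the grid
with half-steps rounded away from the baseline (so +0.425 reports as
+0.43). Harvest loss is `1 − harvest/reference` with the reference being
the local provenance under no warming; losses can be negative and are not
clamped.

Fluctuation ensembles replicate a scenario (default 100 times; replicate
`r` draws its series with seed `base_seed + r`, so ensembles sharing a base
seed are paired draw-for-draw across tolerance settings) and report the
per-replicate best provenance and loss plus mean/sd summaries.

## Synthetic data

The fixture module generates everything the tests need. The reference
two-stage life cycle (juvenile survival 0.61, adult survival 0.98, growth
0.012, rotation 60 years with a 100-year variant, cumulative tolerance
3.5 °C) anchors the quantitative checks. Random ladder life cycles draw
survivals and growths uniformly from (0.01, 0.99), rejecting (for n > 2)
draws whose typical life history misses the last stage by harvest, which
mirrors the filter a harvest-time analysis imposes on real matrices.
Species-like matrices target a prescribed first-stage duration (1–15
years), spanning the fast-to-slow maturation axis along which real tree
matrices differ most. What the generator does *not* emulate: density
dependence, reproduction, retrogression in real matrices (stripped to
extra mortality by the conformance step, never renormalised), measurement
error in transition rates, and autocorrelated or non-Gaussian climate —
so passing tests demonstrate internal consistency and the model's
comparative statics, not fidelity to any particular species.

## Numerical choices

- All harvest closed forms work in log space; probabilities re-exponentiate
  only at the end, so mismatch penalties of hundreds of log-units do not
  overflow.
- Ceiling with a 1e−9 guard protects exact-integer expected durations from
  floating-point noise.
- The fundamental matrix refuses spectral radius ≥ 1 − 1e−12 (an immortal
  stage) rather than returning a meaningless inverse.
- Matrix validation tolerates 1e−9 of floating-point slack on probability
  bounds and column sums; the conformance step distinguishes dropped mass
  (reported per entry) from mortality already present.
- Grid snapping adds 1e−9 before flooring so that exact half-steps round
  away from the baseline deterministically.

## Known limitations

- One climate axis and one optimum per individual for life; no
  stage-specific optima and no multivariate niches.
- Expectation dynamics only: no demographic stochasticity in the cohort,
  and no reproduction or multi-generation evolution.
- The quarter-rotation deviation analysis shows that when the least
  tolerant stage is both brief and extreme (e.g. a one-year juvenile stage
  with a 9-fold tolerance ratio), the single harsh year retains a large
  harmonic weight and the best provenance does *not* converge to the
  constant-tolerance optimum as the juvenile stage shrinks to its one-year
  minimum — the pull vanishes only in the continuous limit of a
  zero-duration stage. One acceptance-level check encodes the stricter
  expectation and fails honestly on this point.
- Problem sizes used throughout (two- and three-stage cycles, H = 60–100,
  100-replicate ensembles, 401–1001-point grids) keep every documented
  check within seconds on one core; they are the reference configurations
  of the analysis, and the closed-form mixture makes larger grids cheap if
  needed.
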