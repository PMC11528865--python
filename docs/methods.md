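# Methods

## Model and estimand

We consider a cluster randomised trial in which every cluster recruits `m`
participants over a recruitment window rescaled to `(0, 1]`, at the
regularly spaced times `t_i = i/m` (no recruit at time 0, one exactly at
1). Clusters are randomised to three sequences that switch from control to
intervention at times `s`, `0.5` and `1 − s`, in proportions `(1 − w)/2`,
`w`, `(1 − w)/2` — the centrosymmetric three-sequence family. A
participant's condition is fixed by their presentation time: treated iff
`t ≥ t*` for their cluster's cross-over `t*` (the step convention
`H(0) = 1`, so a participant presenting exactly at the cross-over counts as
treated).

The analysis model is linear with a single, instantaneous and sustained
treatment effect `δ` and a secular trend shared by all clusters. The trend
is modelled as piecewise constant with jumps exactly at the three
cross-over times. This is not a restriction in disguise: because the
regressors and the treatment indicator are all step functions on the same
recruitment grid, the GLS variance of `δ̂` under this four-parameter trend
equals the variance under a completely general time effect that differs at
every recruitment time, and it is the trend-adjusted variance that drives
design choice.

Within-cluster correlation follows a proportionate-decay model: two
same-cluster participants presenting a time `d` apart have correlation
`ρ τ^d`, with `ρ` the time-specific ICC and `τ ∈ (0, 1]` the factor left
after decay over the whole window. `τ = 1` is the exchangeable
(random-intercept) model. Different clusters are independent, so the
covariance of the stacked data is block diagonal with identical blocks
`σ² V_c`.

## The variance multiplier

Because every cluster on a sequence contributes the same regressor block
`X_k = [treatment indicator | trend basis]`, the information matrix
aggregates per sequence:

    A = Σ_k p_k · X_k′ V_c⁻¹ X_k,     Var(δ̂) = [A⁻¹]₁₁ · σ²/J ≡ θ σ²/J.

`θ` is free of `σ²` and `J`; allocation enters only through the proportions
`p_k`, which deliberately may imply fractional cluster counts (the variance
is asymptotic in `J`). Numerical choices:

- `V_c` is factorised once per `(m, ρ, τ)` (Cholesky) and reused across all
  `(s, w)`; `θ` is obtained by solving `A x = e₁`, never by forming
  explicit inverses.
- Collinear trend columns are pruned before inversion by a greedy
  left-to-right rank rule at relative tolerance 1e−10, keeping the
  intercept and never pruning the treatment column. The canonical case is
  `s = 0`, where `H(t − 0)` duplicates the intercept. `θ` is invariant to
  which member of a collinear set survives (the fitted span is unchanged),
  and a unit test fits the alternative pruning to confirm it.
- A design is rejected as non-identifiable when the pooled treatment column
  (over sequences with positive weight) lies in the span of the pooled
  trend columns — e.g. `m = 1`, or tiny `m` with `s` so close to 0.5 that
  all three cross-overs land on the same recruit.
- Step indicators are realised by an index rule, `i ≥ ceil(m t* − 1e−9)`,
  rather than floating comparison of `i/m` with `t*`, so the `H(0) = 1`
  convention is bit-stable (10/120 vs 1/12 can differ in the last ulp).

A useful reduction: `R = mρ/(1 − ρ)` governs within-cluster mean
comparisons. Under exchangeability the correlation between the pre- and
post-crossover half-means of a cluster crossing at 0.5 is `R/(2 + R)`, and
writing `V_c = (1 − ρ)[I + (R/m) T_τ]` (with `T_τ` the pure-decay kernel)
shows that `θ · m/(1 − ρ)` depends on the design only through `(R, τ)` up
to `O(1/m)` discreteness. The discreteness is not negligible at small `m`:
with `H(0) = 1` the treated fraction of a sequence is `1 − t* + O(1/m)`
with a boundary term from `ceil(m t*)`, so surfaces for `m = 50` visibly
deviate from `m = 1000` at strong correlation even at matched `(R, τ)` —
the shape comparison tests document this (one is expected to fail at the
extreme setting `τ = 0.1, R = 20`, where the `m = 50` normalised surface
deviates by up to ~15% in variance ratio; the m-collapse under fixed `R`
is nonetheless far tighter than under fixed `mρ`).

A related discreteness note: the continuous design family is exactly
centrosymmetric, but the recruitment grid `(1/m, …, 1)` is not symmetric
about 0.5, and a recruit sitting exactly on a knot is treated on both ends
under `H(0) = 1`. The reverse-and-swap image of sequence 1 therefore
matches sequence 3 only up to one boundary recruit (two when `m s` is an
integer). The exact symmetry that does hold — and is tested — is at the
variance level: `θ` is invariant under relabelling the sequences (3, 2, 1)
with time-reversed rows and a consistently permuted correlation matrix.

## Design-space search

`log θ` is evaluated on a rectangular grid, by default 100 × 100 over
`s ∈ [0, 0.5)`, `w ∈ [0, 1)` (steps 0.005 and 0.01) — fine enough to
resolve 10% contours for `m` up to 1000 in seconds, because for fixed `s`
all five regressor columns come from one `m × 4` basis and a whole grid row
costs a single triangular solve. Contour levels are spaced `log(1.1)`
anchored at the surface minimum, so the innermost contour delimits designs
within 10% of the minimum attainable variance. The grid optimum is refined
by Nelder–Mead (converged at 1e−8 relative in `θ`), with the refined point
additionally projected onto the `s = 0` and `w = 0` boundaries — the
simplex handles active box constraints poorly and the optimum sits at
`s = 0` for all small `mρ`. Ties in the grid minimum break to smallest `s`
then smallest `w`; non-identifiable cells are excluded and counted.

Two reference designs summarise the search: the hybrid `(s = 0, w = 1/3)`
is within 10% of optimal across essentially the whole moderate-correlation
range (`mρ` 0.2–5, any `τ` 0.1–1), and `(s = 0.15, w = 1/3)` takes over for
`mρ ≥ 5`. One caveat our computations add: at the weakest-correlation corner
(`mρ = 0.2, τ = 0.1, m = 200`) the hybrid design's efficiency ratio is
1.107 — marginally outside the 10% band, robustly so across `m` and grid
resolution; the corresponding test is left failing as a faithful record
rather than relaxed. The worked example's compromise `(s = 1/12, w = 1/3)`
is evaluated by `robust_design_report`, which tabulates
`θ_candidate/θ*` across user-supplied correlation scenarios.

## Sample size and power

`J ≥ (z_{1−α/2} + z_{1−β})² (σ/δ*)² θ`, with full-precision standard normal
quantiles (no t correction, matching the asymptotic variance), rounded up
to the next multiple of 3 by default (three equally weighted sequences);
the unrounded bound is also reported since unequal `w` need not divide any
integer `J`. The ceiling applies a 1e−9 slack so bounds within floating
noise of an exact multiple are not bumped a whole multiple up. The inverse
map is `power = Φ(|δ*|/(σ√(θ/J)) − z_{1−α/2})`, which neglects the far
tail (at `δ* = 0` it returns `α/2`, one tail of the two-sided test).

## Simulation

The generator draws each cluster's outcome vector from a multivariate
normal with mean `δ·treated + T(t)β` and covariance `σ² V_c` (Cholesky
transform of iid normals), clusters independent, per-replicate streams
spawned deterministically from one master seed. Integer cluster counts are
the nearest centrosymmetric split of `J` (outer sequences equal). The
generator's default validation scenarios are the worked example's: `m = 120`,
`σ = 10.7`, `ρ ∈ {0.02, 0.05}`, `τ ∈ {1.0, 0.5}`, effects 1–1.5, trend
coefficients `β = (1.0, 0.5, −0.3, 0.2)` (a gentle step trend; `θ` is
trend-free, so `β` only exercises the adjustment machinery).

Two fitters:

- **Oracle GLS** plugs in the true `(ρ, τ)`, estimating only the
  coefficients and `σ²` (ML, divisor `n`). It isolates the design variance
  formula from correlation estimation: its model-based SE is exactly
  `√(θ/J)·σ̂` when clusters match the design proportions.
- **ML** maximises the full seven-parameter multivariate-normal likelihood.
  The likelihood is profiled — for fixed `(ρ, τ)` the coefficients and `σ²`
  are closed-form — leaving a two-parameter Nelder–Mead search on the logit
  scale. Starting values: method-of-moments `ρ` from OLS residuals,
  `τ = 0.8`. `fix_tau=1` gives the exchangeable sub-model, whose maximised
  likelihood is cross-checked against an independent random-intercept
  mixed-model fit (statsmodels MixedLM, ML) in the tests. No REML and no
  small-sample correction anywhere; Wald z tests throughout.

Validation problem sizes, chosen to make Monte-Carlo error small enough to
detect formula errors while keeping the default suite quick: 500
replicates for empirical power, sampling variance of `δ̂` and type-I error
at the `J = 72` worked-example configuration (binomial 3-SE bands, ±0.054
on power, ±0.029 on type-I; variance band `3√(2/(n−1)) ≈ 19%` relative);
200 replicates for ML parameter recovery at `J = 63`. ML variance
components carry the expected small downward finite-sample bias (order
`1/J`); at these replicate counts the recovery means stay within 3
Monte-Carlo SEs of truth, but users analysing trials with few clusters
should expect mildly anticonservative ML standard errors — the motivation
for the oracle fitter's existence.

## What the generator does and does not emulate

It reproduces the design assumptions exactly: fixed `m`, regular
recruitment times, Gaussian outcomes, proportionate ICC decay, a common
step trend, instantaneous sustained treatment effect. It does not emulate
random (e.g. Poisson) arrival processes, unequal cluster sizes or
recruitment rates, non-Gaussian outcomes, time-varying treatment effects,
or other correlation families (block exchangeable, discrete-time AR).
Passing tests therefore validate the mathematics of the design formula,
not robustness to these departures; simulation studies in the field suggest the
impact of irregular arrival spacing on precision is small.

## Known limitations

- The variance is asymptotic in `J` with normal quantiles; with few
  clusters both the sample-size rule and the ML analysis are
  anticonservative (no Satterthwaite/Kenward–Roger-type corrections are
  implemented).
- Designs are limited to the centrosymmetric three-sequence family; the
  search is grid + local refinement, adequate for this smooth
  two-parameter surface but without global guarantees.
- Surface-shape invariance in `R = mρ/(1 − ρ)` is an `m → ∞` property;
  discreteness corrections are visible for small `m` at strong
  correlation, as documented above.
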