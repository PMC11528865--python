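# swcr — three-sequence stepped wedge designs with continuous recruitment

`swcr` is a design and power toolkit for stepped wedge cluster randomised
trials in which participants are recruited in a continuous stream rather
than in discrete measurement periods. It targets the simplest interesting
case: three sequences, with the design constrained to be *centrosymmetric*
(reversing time and swapping intervention/control labels reproduces the
design). Such a design is fully described by two numbers on the unit-scaled
recruitment interval:

- `s` — the time of the first cross-over (the sequences cross at `s`, `0.5`
  and `1 − s`), with `0 ≤ s < 0.5`;
- `w` — the proportion of clusters allocated to the middle sequence (the
  outer sequences each take `(1 − w)/2`), with `0 ≤ w < 1`.

The familiar equally spaced 1:1:1 design is `(s, w) = (1/4, 1/3)`; `s = 0`
gives a *hybrid* design in which the outer sequences act as parallel-group
arms.

## Model

Each cluster recruits `m` participants at regularly spaced times
`t_i = i/m`. The outcome of participant `i` in cluster `j` follows

    Y_ij = δ·H(t_ij − t*_j) + T(t_ij) + ε_ij,    ε_ij ~ N(0, σ²)

where `t*_j` is the cluster's cross-over time, `H` is the unit step function
with `H(0) = 1`, and `T` is a piecewise-constant secular trend with jumps at
the three cross-over times,
`T(t) = β₁ + β₂H(t − s) + β₃H(t − 0.5) + β₄H(t − 1 + s)`.
Within a cluster the correlation between two participants presenting a time
`d` apart is

    Corr(ε_ij, ε_i'j) = ρ·τ^d

— `ρ` is the time-specific ICC and `τ` the factor by which it has decayed
over the whole recruitment interval (`τ = 1` is the exchangeable model).
Clusters are independent, so the GLS variance of the treatment effect
estimator, adjusted for the trend, aggregates per sequence and takes the
form

    Var(δ̂) = θ(s, w; m, ρ, τ) · σ²/J

with `J` the number of clusters. The dimensionless multiplier `θ` —
the leading element of the inverse information matrix
`Σ_k p_k X_k′ V⁻¹ X_k` — is the core quantity: lower `θ` means a more
efficient design, and the number of clusters for power `1 − β` at two-sided
level `α` follows from

    J ≥ (z_{1−α/2} + z_{1−β})² (σ/δ*)² θ,

rounded up to a multiple of three. The package maps `log θ` over the
`(s, w)` design space, finds optimal and near-optimal designs (within 10%
of the minimum variance), converts `θ` to cluster counts, and validates the
theory by Monte-Carlo simulation with either a known-correlation GLS fit or
a full maximum-likelihood fit of the seven-parameter model.

## Worked example

A weight-loss intervention is rolled out across primary-care clinics that
each identify 30 eligible patients per year for 4 years (`m = 120`). The
outcome SD is 10.7 kg, and the time-specific ICC is thought to lie between
0.02 and 0.05 with a decay of up to 0.5 over the 4 years. Compare the
standard equally spaced design with a design that pulls the outer
cross-overs towards the ends (`s = 1/12`, i.e. switching on after 4 months,
2 years, and 3 years 8 months):

```
$ swcr table1
 rho  tau  theta_non_standard  J_non_standard_1kg  J_non_standard_1.25kg  J_non_standard_1.5kg  theta_standard  J_standard_1kg  J_standard_1.25kg  J_standard_1.5kg
0.02  1.0              0.0793                  72                     48                    33          0.1002              93                 60                42
0.02  0.5              0.0820                  75                     48                    33          0.1054              96                 63                45
0.05  1.0              0.0928                  84                     54                    39          0.1054              96                 63                45
0.05  0.5              0.1094                  99                     63                    45          0.1217             111                 72                51
```

Each row is one correlation scenario. `theta_*` is the variance multiplier
of the design; the `J_*` columns are the clusters needed to detect a 1,
1.25 or 1.5 kg mean difference with 80% power at the 5% level. The
non-standard design beats the standard one in every scenario — e.g. at
`ρ = 0.02, τ = 1.0` it needs 72 clinics instead of 93 to detect a 1 kg
effect. Other entry points:

```
swcr variance --s 0.0833333 --w 0.3333333 --m 120 --rho 0.02 --tau 1.0
swcr surface  --m 200 --mrho 5 --tau 0.5 --out surface.csv --plot surface.png
swcr optimum  --m 200 --mrho 2 --tau 1.0
swcr samplesize --theta 0.0793 --delta 1 --sd 10.7
swcr simulate --s 0.0833333 --w 0.3333333 --m 120 --rho 0.02 --tau 1.0 \
              --delta 1 --sd 10.7 --j 72 --reps 1000 --seed 1 --fitter oracle
```

`swcr optimum --m 200 --mrho 2 --tau 1.0` prints
`{"s": 0.0, "w": 0.3327731049600988, "theta": 0.04469946513206729}`: at
moderate correlation the optimal design is a hybrid — first cross-over at
time zero, a third of clusters in the middle wedge.

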