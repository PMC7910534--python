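# Methods

## Spatial primitives

Regions are point population centres.  Distances are Euclidean on
projected kilometre coordinates, or great-circle (haversine, Earth
radius 6371 km) on longitude/latitude; road distance and travel time
are out of scope.  The intervening population `s_ij` is the total
population of regions strictly inside the circle centred at the
*origin* `i` with radius `r_ij`, excluding both endpoints.  Two
conventions are fixed deliberately: the circle is origin-centred (the
standard radiation-model reading; a union of circles around both
endpoints would be an alternative), and ties at exactly `r_ij` are
excluded (strict inequality), so a region co-located with the
destination never counts as intervening.

## Base models and their quirks

All five flux equations are evaluated per ordered pair and assembled
into a matrix with an exactly-zero diagonal — within-region flows are
not modelled, so the diagonal carries no information anywhere in the
pipeline.

* **Gravity** `θ m^α n^β / r^γ`: the exponents are free reals; a zero
  distance with `γ > 0` is an error the caller must route to the
  self-loop rule, not a value.
* **Gravity with distance cut-off**: two full gravity parameter sets
  switched at `δ`; the boundary `r = δ` is assigned to the short-range
  branch (the half-open split must land somewhere; this is the fixed
  contract).  `δ` is fitted on a log scale by default and can be frozen
  via `FitConfig.fix_delta`.
* **Radiation** `θ m n / ((m+s)(m+n+s))`: `θ` is nominally the
  commuting proportion, but it is fitted as a free positive scale
  because normalised intensity data (which sum to one) make the
  proportion reading meaningless.
* **Radiation with selection** `θ (1−λ^P/P)(1−λ^Q/Q)/(1−λ^R/R)` with
  `P = m`, `Q = n`, `R = m+n+s` and `λ ∈ (0,1)`.  `λ^P` is computed as
  `exp(P log λ)` and underflows cleanly to zero for city-sized
  populations, where each factor tends to 1 and the flux tends to the
  constant `θ`.  This near-degeneracy at realistic population sizes is
  a property of the equation itself, not a bug: on such data the model
  contributes little beyond an intercept, and in the stacker its
  near-collinearity with other predictors legitimately produces large
  offsetting weights.
* **Intervening opportunities** (stochastic form)
  `κ (e^{−λ(s+m)^θ} − e^{−λ(s+m+n)^θ})`: `e^{−λ}` is the probability a
  single opportunity is rejected; the proportionality constant `κ` is
  made explicit because Poisson fitting needs an absolute scale.  The
  opportunity count ahead of the destination is taken as `s + m`, i.e.
  the origin's own population plus the intervening population.

## Fitting

Parameters are estimated by minimising the Poisson negative
log-likelihood `Σ(μ − y log μ)` over off-diagonal cells (the `log y!`
term is constant in the parameters and dropped).  Observations may be
non-integer — the same kernel is a valid quasi-likelihood for
normalised intensities.  Zeros are data; cells can be excluded from the
sum with an explicit mask, which is how cross-validation hides held-out
cells (masking, not zero-filling, which would bias the scale downward).
Predictions are floored at `ε = 1e−10` before any logarithm; the same
constant is used in the stacker's design matrix.

The optimiser is BFGS with central-difference (3-point) numerical
gradients on transformed parameters: `log` for positive scales and
rates (`θ`, `κ`, the IO `λ` and exponent, `δ`), `logit` for the
selection `λ`, identity for the exponents `α, β, γ`.  One important
numerical choice: each model factorises as `scale × f(shape)`, and for
fixed shape the Poisson-ML scale has the closed form `Σy / Σf` (per
branch for the distance-cut-off model).  The scale is therefore
concentrated out of the likelihood analytically at every objective
evaluation, and BFGS only ever searches the shape space.  Without
this, the IO model's likelihood surface has a long curved ridge
(trading `κ` against `λ` and the exponent) on which quasi-Newton steps
stall; with it, all five fits converge in tens of iterations.

Starting values are data-driven: unit exponents, the scale matched to
the observed mean flow, `δ` at the median off-diagonal distance,
selection `λ = 0.5`, and the IO `λ` set so retention halves at the
median opportunity count.  Failed starts are retried (default 3
restarts) with seeded Gaussian jitter, so fitting is deterministic
given `FitConfig.seed`.  A fit that never meets the gradient tolerance
is returned with `converged=False` plus a warning — never silently.
All-zero observations are legal degenerate input: the scale collapses
to the floor and a warning is emitted.

## The stacked ensemble

The stacker is a log-link Poisson GLM of the observed flows on the
five base models' log-predictions (fixed column order: gravity,
gravity-with-distance, radiation, radiation-with-selection,
intervening opportunities).  Diagonal cells are excluded from both
fitting and prediction — base predictions there are identically zero
and their logarithm is undefined; exclusion is the only consistent
treatment.  The GLM is fitted by IRLS with deviance-based step-halving
and pseudo-inverse solves, so collinear or near-collinear columns are
*kept*: when two base models make nearly identical predictions the
optimum weight vector is nearly unidentified along their difference
and the fitted weights can be huge and offsetting, which is faithful
behaviour, not an error.  An optional ridge penalty (`EnsembleConfig.
ridge`, default 0) is available when stable individual weights matter
more than fidelity.  Predictions `μ = exp(β₀ + Σ β_a log λ_a)` are
capped at `1e15` with a warning if the linear predictor overflows.

Because the GLM's feasible set contains every "pure" weighting
(`β_a = 1`, rest 0), the fitted stacker's *training* deviance can never
exceed any single base model's.  No such theorem covers the
equal-weight arithmetic mean — the GLM spans geometric, not
arithmetic, combinations — yet the fitted ensemble beats that baseline
too on all fixtures tested here, and the held-out advantage over the
best base model is the pipeline's headline empirical property,
measured (never assumed) by cross-validation.

## Evaluation

k-fold cross-validation (default `k = 5`) partitions the off-diagonal
*cells* — not the regions — uniformly at random (seeded, fold sizes
within one).  Per fold, the base models are refitted with held-out
cells masked out of the likelihood; the ensemble is stacked on those
fold-fitted predictions using the same training cells (no leakage);
every model, plus the unweighted mean of the five base predictions, is
scored on the held-out cells with the Poisson deviance
`2 Σ[y log(y/μ) − (y − μ)]` (the `y = 0` term takes its limit `2μ`; the
`ε` floor applies only inside the logarithm so a perfect fit scores
exactly zero, and the sum is clamped at zero against floating-point
cancellation).  Deviance is a *relative* measure: the report compares
models within one dataset and never aggregates across datasets.  A
non-convergent base fit marks its fold as degraded in the report; the
run continues.

## Synthetic data

The generator emulates regional commuting data without any download:
populations log-uniform on [3,000, 25,000] (the size band of Australian
SA2 statistical regions; the log-uniform law is this package's
stand-in for the heavy-tailed urban/rural contrast, as no generative
law is prescribed by the setting it emulates), coordinates uniform on a
500 km square or Gaussian (σ = 25 km) around uniformly placed hubs,
expected flows from one base model or a convex mixture, independent
Poisson noise per off-diagonal cell, and two regimes: `census_like`
integer counts and `gps_like` matrix-normalised intensities.
Expectation mode (`noise="expectation"`) passes the exact mean matrix
through untransformed — a noise-free diagnostic used for
parameter-recovery closure tests.  Mixtures are first-class because
the ensemble only has something to gain when no single base model is
true; the reference scenario is a 50/50 gravity + intervening-
opportunities mixture.

Default generating parameters were chosen once for realism at this
scale: gravity `θ = 0.3, α = 0.8, β = 0.6, γ = 1.5` gives typical cell
counts in the tens with a heavy short-range/thin long-range contrast;
IO `κ = 300, λ = 0.02, θ = 0.5` gives comparably scaled counts with
the much steeper opportunity-driven decay characteristic of that
model.  What passing tests on these data do *not* show: robustness to
non-Poisson overdispersion, spatially correlated noise, road-network
geometry, or sampling bias of real census/GPS collection — none of
which the generator emulates.

## Problem sizes and determinism

The shipped studies use 40–80 regions: parameter recovery at 50
regions (gravity exponents to ~1e−8 on noise-free data, ~0.005 under
Poisson noise), and the held-out comparison on five independent
60-region mixture replicates with 5-fold CV, where the ensemble's mean
held-out deviance undercuts the best base model in ≥ 4 of 5
replicates.  These sizes estimate every quantity stably while keeping
a full study in seconds; the method itself is O(n²) cells per fit and
has no scale-specific constants.  Every random choice — locations,
noise, fold assignment, restart jitter — flows from explicit integer
seeds, and the whole CLI chain is byte-deterministic given the
configured seed (run logs carry the timestamp; data artifacts do not).

## Known limitations

* Straight-line distances; no road networks or travel times.
* No production/attraction-constrained gravity variants.
* The stacker is the plain GLM stacker — no cross-validation *within*
  stacking (super-learner variants) and, by default, no regularisation.
* Unweighted likelihood: every off-diagonal cell counts equally, with
  no treatment of structural zeros beyond the optional mask.
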