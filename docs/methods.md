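# Methods

## The problem

Ecological monitoring programs rarely sample uniformly: stratified and other
unequal-probability designs buy precision for the population means and trends
they were designed around. When the same data are later fed to *model-based*
tools — multiple regression, quantile regression, boosted regression trees —
those tools implicitly assume every unit entered the sample with the same
probability. If the inclusion probability `P_i` is correlated with the
quantity being modeled, ignoring it biases the fit toward the
over-represented units.

## Inverse probability bootstrap (IPB)

Given a probability sample of size `N` in which row `i` carries its
inclusion probability `P_i ∈ (0, 1]`, define resampling weights

    w_i = (1 / P_i) / Σ_j (1 / P_j),

i.e. the inverse inclusion probabilities normalized to sum to one. An IPB
resample draws `N` rows from the sample **with replacement** with
probabilities `w_i`. Composed with the original design, every population
unit has the same expected appearance rate in the resample (`n / N_pop`),
so the resample behaves as an equal-probability sample for model-based
estimation. Resampling with replacement is essential: without replacement
the "resample" would simply reproduce the original sample.

The estimation loop mirrors a conventional bootstrap: repeat
(resample → fit), average the named coefficients across iterations for the
point estimate, and report the across-iteration standard deviation as the
bootstrap standard error. The SE estimates a property of the *sample size*,
not of the iteration count, and does not shrink as iterations grow (this is
tested by comparing SEs at 500 vs 5000 iterations).

**Inflated sampling.** Estimators whose "parameters" cannot be averaged
across fits (tree ensembles) instead use a single resample of size
`round(f · N)` for an inflation factor `f ≥ 1` (default 100 for single-fit
use; the scaled-down validation experiments here use smaller factors).
The fit remains unbiased, but the apparent sample size overstates the
information content by `f`, so model-reported standard errors are invalid;
such samples are flagged `inflated` and SE reporting is suppressed.
Corrected SEs for inflated samples are out of scope; use cross-validation
for precision assessment.

**RNG contract.** Every stochastic operation takes an explicit
`numpy.random.Generator` or seed. Iterated runs derive iteration `i`'s
stream as `default_rng(SeedSequence([seed, i]))`, so any iteration is
reproducible on its own and results are bit-identical across runs.

**Failure policy.** Bootstrap resamples of small samples can be degenerate
(collinear duplicated rows). Singular fits are dropped and counted; a run
aborts if more than 5% (configurable) of iterations fail.

## Estimators

* **OLS** — `numpy.linalg.lstsq`; agrees with the normal-equations solution
  to 1e-8 and raises a singular-fit error on rank deficiency.
* **Quantile regression** (default τ = 0.95, the upper tail used for
  carrying-capacity-style questions) — exact linear program
  `min τ·Σu + (1−τ)·Σv  s.t.  Xβ + u − v = y, u,v ≥ 0` solved with HiGHS.
  The solver returns a vertex; for intercept-only fits with `n·τ` integral
  this is the lower of the two optimal order statistics, which is the
  convention this package documents and pins in tests. On small instances
  the returned fit attains the brute-force-optimal check loss over all
  point-pair interpolants.
* **Boosted regression trees** — stagewise least-squares gradient boosting
  of depth-limited trees (scikit-learn). Defaults: 500 trees, depth 3,
  learning rate 0.05, subsample 0.5 — unpublished upstream, so chosen as
  conservative, standard values; every qualitative claim about BRT is
  insensitive to them and only the bias *pattern* (biased when
  probabilities are ignored, unbiased under IPB) is treated as
  reproducible. A constant response yields a mean predictor, not an error.

## Validation machinery

**Leave-one-out bias.** Against a known finite population: hold out each
unit, draw a *fresh* sample from the remaining units under the strategy
being assessed (one draw per held-out point), fit, and predict the held-out
response. Errors are `predicted − observed`; the mean error over the
population is the strategy's bias and their SD its precision. When
validation points come from an unequal-probability sample, the weighted
mean `Σ(e_i/P_i) / Σ(1/P_i)` is used instead, which reduces exactly to the
plain mean under uniform probabilities. Bias magnitudes, not signs, are the
comparable quantity across published summaries of these experiments, whose
sign conventions are not internally consistent.

**Inclusion-frequency experiments.** Replicate (stratified draw [→ IPB
resample]) many times and track each unit's mean appearance count per
replicate. For the without-replacement design stage counts are 0/1 and this
is the ordinary inclusion frequency (≈ `n_h/N_h` per stratum); for the
with-replacement IPB stage multiplicities count, and the analytic value is
`P(selected) · E[count | selected] = (n_h/N_h) · N·w_h = n/N_pop` — uniform
across all units, 0.20 for the 20-of-100 design. (Counting mere presence in
the resample would *not* be uniform, because with-replacement multiplicity
is how IPB rebalances the strata.)

**COV sweep.** The coefficient of variation (population SD / mean) of the
per-unit inclusion probabilities summarizes how unequal a design is. The
sweep rescales the stratum probabilities linearly about their mean —
`p_h(t) = p̄ + t(p_h − p̄)` scales the COV by exactly `t` while preserving
the stratification structure — and runs the LOO experiment per grid point.
Naive-fit bias grows monotonically with COV; IPB bias stays within
Monte-Carlo noise of zero everywhere.

## The synthetic populations

**Frequency-experiment population:** 100 units in four strata of 25, with
per-stratum sample sizes 2/3/6/9, hence inclusion probabilities
0.08/0.12/0.24/0.36 and 20 sampled units overall.

**Correlated ecological population:** 1400 units with response `Y` and six
covariates `X1..X6`, multivariate normal with mean `(2,4,3,2,2,3,8)` and
the non-diagonal covariance used throughout (notably `cov(Y, X3) = 3.0`).
Five strata A–E are cut along increasing `Y` at the published stratum
counts 435/183/182/143/457, with per-unit probabilities
0.71/0.36/0.18/0.18/0.14 — a probability COV of 0.70. Probability-specified
designs are realized as fixed per-stratum sizes `n_h = round(p_h · N_h)`
(total n = 498), which matches without-replacement sampling and makes
replicate frequency checks exact.

**Between-cluster dispersion.** Real ecological metrics are clustered, and
the reference data for this configuration were generated with a clustering
generator whose settings were not published. A plain draw from the
covariance table alone demonstrably does not reproduce the published
population regression slopes of `Y` on `X1..X6` (it gives e.g. 0.534 for X3
versus the published 0.436). The generator therefore adds an independent
mean offset per covariate with diagonal variance `D`, derived in closed
form from the published slopes `β*`:

    D_j = (σ_xy − Σ_xx β*)_j / β*_j ,

the unique diagonal inflation of the covariate covariance under which the
population slopes equal `β*`. All entries come out nonnegative, which is
consistent with independent between-cluster offsets. Two caveats, by
construction rather than accident:

* the response's own between-cluster dispersion is *unidentifiable* from
  the slopes and is left at zero (the parsimonious choice); consequently
  prediction-error SDs here are ≈ 0.77 rather than the ≈ 1.07 of the
  reference experiments, while bias magnitudes (the quantities under study)
  reproduce — the three strategies' error SDs remain within 10% of one
  another, which is the comparison that matters;
* the X5 entry of `D` is poorly determined because its slope is nearly
  zero; it merely inflates the variance of a covariate with negligible
  effect.

By default offsets are drawn per unit, which realizes the same population
covariance as a many-cluster geometry; an explicit `n_clusters` shares
offsets within clusters for sensitivity analysis. What passing tests under
this generator do **not** show: robustness to cluster geometries whose
offsets correlate across variables, to non-normal responses, or to
misspecified inclusion probabilities — none of which the generator
emulates.

Stratum boundaries rank units by `(response, unit_id)` with a stable sort,
so boundary ties resolve to the lower-labeled stratum, deterministically.

## Problem sizes and numerical choices

* Frequency experiments: 100,000 replicates (400,000 for the per-unit
  uniformity check, where per-unit Monte-Carlo SE must sit well below the
  ±0.005 band being asserted).
* LOO bias experiments: full 1400-point passes; 2–4 passes averaged; 50 IPB
  iterations per fit (the bias of the IPB mean estimate does not depend on
  the iteration count; iterations only add averageable noise). The COV
  sweep uses 400-point held-out subsets × 3 replicates per grid point.
  These sizes put Monte-Carlo SEs of bias estimates at ~0.01–0.03, an order
  of magnitude under the ≈ 0.3 naive-strategy bias being measured.
* Weight invariants (sum to 1, proportionality to `1/P_i`) are enforced at
  1e-12 at construction; OLS/normal-equations agreement at 1e-8; quantile
  LP optimality at 1e-9 against brute force.
* Degenerate inputs: zero/negative/missing probabilities are rejected at
  container construction with the offending row indexed; a census design
  (`P_i = 1`) is valid and IPB then reduces to the ordinary bootstrap of a
  uniform sample.

## Known limitations

* Standard errors under inflated sampling are suppressed, not corrected.
* Joint inclusion probabilities (multi-stage/cluster designs), spatially
  balanced designs, finite-population corrections, and raking/
  post-stratification for *estimating* unknown probabilities are out of
  scope; probabilities are taken as known inputs.
* Quantile-regression LOO bias is only meaningful against a reference
  surface (there is no per-point observed quantile); the package follows
  the standard device of comparing against a linear model fit to the full
  population, and treats such comparisons as approximate.
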