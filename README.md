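# ipboot — inverse probability bootstrap sampling

Ecological (and other survey) data are usually collected under
unequal-probability designs: stratified sampling over-samples the strata
that matter for the monitoring objective. Model-based analysis tools —
linear regression, quantile regression, boosted regression trees — assume
instead that every unit entered the sample with equal probability. When the
inclusion probability `P_i` correlates with the modeled quantity, ignoring
it produces selection-biased parameter estimates.

`ipboot` implements the **inverse probability bootstrap (IPB)**: resample
the unequal-probability sample *with replacement* using normalized inverse
inclusion probabilities

```
w_i = (1 / P_i) / Σ_j (1 / P_j)
```

Each resample is an equal-probability sample, so any model-based tool can
be applied unchanged. Estimates are averaged over resamples (bootstrap
iterations), with across-iteration SDs as standard errors; estimators that
cannot be averaged (tree ensembles) use a single *inflated* resample
instead, whose point estimates are valid but whose model-reported SEs are
suppressed. The method corrects the *sample*, not the analysis tool, which
is what makes it generic.

The package also ships the machinery to demonstrate the bias and its
elimination on synthetic populations: stratified/SRS samplers with exact
inclusion-probability bookkeeping, a correlated 7-variable population
generator, leave-one-out cross-validation bias estimation (with
inverse-probability-weighted error averaging for real-data use), replicate
inclusion-frequency experiments, and a bias-versus-probability-COV sweep.
See `docs/methods.md` for the model, assumptions, and numerical choices.

## Worked example

Draw a stratified sample whose inclusion probabilities range 5× across
response strata (probability COV 0.70), fit ordinary regression naively,
then correct it with IPB:

```python
import numpy as np
from ipboot import (
    EstimatorSpec, ProbabilitySample, draw_stratified_sample, generate_population,
    inclusion_probabilities, probability_cov, run_ipb, stratify_by_response,
)
from ipboot.estimators import fit_ols
from ipboot.population import sim2_population_spec, sim2_stratification

# a 1400-unit correlated population with known regression structure
frame = generate_population(sim2_population_spec(seed=42))

# stratify on the response and draw an unequal-probability sample
design = stratify_by_response(frame, sim2_stratification())
print(f"design probability COV: "
      f"{probability_cov(inclusion_probabilities(frame, design)):.2f}")
sample = draw_stratified_sample(frame, design, rng=42)

# population truth, the naive fit, and the IPB-corrected fit
census = ProbabilitySample(
    unit_id=frame.unit_id, response=frame.response, covariates=frame.covariates,
    covariate_names=frame.covariate_names, inclusion_prob=np.ones(frame.n),
)
truth = fit_ols(census).coefficients
naive = fit_ols(sample).coefficients
ipb = run_ipb(sample, EstimatorSpec("ols"), n_iter=1000, seed=0)

print(f"{'':12}{'population':>11}{'naive':>8}{'ipb':>8}{'ipb se':>8}")
for name in ("intercept", "X3", "X6"):
    print(f"{name:12}{truth[name]:11.3f}{naive[name]:8.3f}"
          f"{ipb.mean_estimate[name]:8.3f}{ipb.se_estimate[name]:8.3f}")
```

Output:

```
design probability COV: 0.70
             population   naive     ipb  ipb se
intercept         1.246   1.026   1.325   0.119
X3                0.436   0.417   0.442   0.014
X6               -0.086  -0.084  -0.089   0.011
```

The naive intercept is shifted by ≈ −0.22 (the strata over-sample low
responses), roughly twice the IPB standard error; the IPB estimates sit
within one bootstrap SE of the population values. A single sample shows a
single draw; the leave-one-out experiments (`ipboot.validation.loo_bias`)
quantify the systematic effect — naive prediction bias ≈ 0.28 at
probability COV 0.7 versus ≈ 0.00 for both simple random sampling and IPB,
with indistinguishable error SDs.

## Command line

```
ipboot simulate --n 1400 --seed 1 --out pop.csv
ipboot sample   --frame pop.csv --design design.yaml --seed 2 --out sample.csv
ipboot resample --in sample.csv --seed 3 --out equalized.csv
ipboot fit      --in sample.csv --estimator ols --iters 1000 --seed 4 --out est.json
ipboot validate --frame pop.csv --design design.yaml --strategy ipb --seed 5 --out rep.json
ipboot sweep    --frame pop.csv --design design.yaml --cov-grid 0,0.25,0.5,0.75,1.0 \
                --holdout 400 --seed 6 --out sweep.csv
ipboot reproduce sim1 --reps 100000 --seed 7 --out freq.csv
```

Design configs are YAML, either explicit unit lists per stratum or a
response-quantile rule; see `ipboot.io.read_design_config`.

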