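"""Bias and precision of sampling + estimation strategies.

Bias is measured by leave-one-out cross-validation against a known finite
population: each unit is held out in turn, a fresh sample is drawn from the
remaining units under the strategy being assessed, the model is fit, and the
held-out response is predicted.  Prediction error is defined as
``predicted - observed``; the *bias* of a strategy is the mean prediction
error over the population (or an inverse-probability-weighted mean when the
validation points themselves come from an unequal-probability sample).

Three strategies are compared throughout:

``srs``
    Simple random sampling — the equal-probability, zero-bias baseline.
``strat_ignore``
    Stratified unequal-probability sampling with inclusion probabilities
    *ignored* during fitting — the practice whose bias this package
    quantifies.
``ipb``
    The same stratified samples transformed by inverse probability
    bootstrapping before fitting (iterated-and-averaged for coefficient
    models, a single inflated resample for tree ensembles).

Reported bias values are compared across strategies on *magnitude*: the
error sign convention here is fixed (predicted - observed), but published
summaries of the same experiments are not internally consistent in sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import inflated_ipb_sample, run_ipb
from .errors import FailureBudgetExceeded, InvalidDesignError, SchemaError
from .estimators import EstimatorSpec, predict
from .sampling import (
    PopulationFrame,
    PreparedStratifiedSampler,
    StratifiedDesign,
    as_rng,
    probability_cov,
)
from .population import StratificationSpec, stratify_by_response

__all__ = [
    "ValidationReport",
    "loo_bias",
    "weighted_bias",
    "inclusion_frequency_experiment",
    "cov_sweep",
    "scaled_stratification",
]

STRATEGIES = ("srs", "strat_ignore", "ipb")


@dataclass
class ValidationReport:
    """Per-point cross-validation errors plus their aggregation.

    ``errors`` has one row per (pass, held-out point) with the point's frame
    ``unit_id``, its design inclusion probability, and the prediction error.
    ``bias`` is the unweighted mean error (the frame is the full population
    here); :meth:`weighted` gives the inverse-probability-weighted version
    used when validation points come from an unequal-probability sample.
    """

    errors: pd.DataFrame  # columns: unit_id, inclusion_prob, error
    bias: float
    error_sd: float
    prob_cov: float
    strategy: str
    family: str
    n_points: int
    n_skipped: int

    def recompute_bias(self) -> float:
        return float(self.errors["error"].mean())

    def weighted(self) -> float:
        return weighted_bias(
            self.errors["error"].to_numpy(), self.errors["inclusion_prob"].to_numpy()
        )

    def mc_se(self) -> float:
        """Monte-Carlo standard error of the bias estimate."""
        return float(self.errors["error"].std(ddof=1) / np.sqrt(len(self.errors)))


def weighted_bias(errors, inclusion_probs) -> float:
    """Inverse-probability-weighted mean prediction error.

    ``sum_i(e_i / P_i) / sum_i(1 / P_i)`` — each validation point is
    weighted by the inverse of its original sample inclusion probability, so
    over-represented points do not dominate the bias estimate.  Reduces
    exactly to the plain mean under uniform probabilities.
    """
    e = np.asarray(errors, dtype=float)
    p = np.asarray(inclusion_probs, dtype=float)
    if e.shape != p.shape or e.ndim != 1 or e.size == 0:
        raise SchemaError("errors and probabilities must be aligned non-empty vectors")
    if not np.isfinite(p).all() or (p <= 0).any():
        raise SchemaError("weighted_bias: all inclusion probabilities must be > 0")
    w = 1.0 / p
    return float(np.sum(w * e) / np.sum(w))


def _loo_predict(
    sampler: PreparedStratifiedSampler | None,
    frame: PopulationFrame,
    strategy: str,
    spec: EstimatorSpec,
    i: int,
    rng: np.random.Generator,
    srs_n: int,
    n_iter: int,
    inflation: float | None,
) -> float:
    """Fit on a fresh sample excluding frame position i; predict row i."""
    row = frame.covariates[i]
    if strategy == "srs":
        # uniform draw from the n-1 remaining rows via index shifting
        j = rng.choice(frame.n - 1, size=srs_n, replace=False)
        j[j >= i] += 1
        sample = _srs_sample(frame, j, srs_n)
        return predict(spec.fit(sample), row)
    assert sampler is not None
    sample = sampler.sample_from_positions(sampler.draw_positions(rng, exclude=i))
    if strategy == "strat_ignore":
        return predict(spec.fit(sample), row)
    # ipb
    if spec.family == "brt" or inflation is not None:
        factor = 10.0 if inflation is None else inflation
        resample = inflated_ipb_sample(sample, factor, rng)
        return predict(spec.fit(resample), row)
    result = run_ipb(sample, spec, n_iter=n_iter, seed=int(rng.integers(2**31)))
    coefs = result.mean_estimate
    b0 = coefs["intercept"]
    slopes = coefs[list(frame.covariate_names)].to_numpy()
    return float(b0 + row @ slopes)


def _srs_sample(frame: PopulationFrame, idx: np.ndarray, n: int):
    from .sampling import ProbabilitySample

    return ProbabilitySample(
        unit_id=frame.unit_id[idx],
        response=frame.response[idx],
        covariates=frame.covariates[idx],
        covariate_names=frame.covariate_names,
        inclusion_prob=np.full(len(idx), n / frame.n),
    )


def loo_bias(
    frame: PopulationFrame,
    strategy: str,
    spec: EstimatorSpec,
    rng,
    design: StratifiedDesign | None = None,
    srs_n: int | None = None,
    n_iter: int = 100,
    inflation: float | None = None,
    holdout: int | np.ndarray | None = None,
    n_passes: int = 1,
    max_skip_frac: float = 0.01,
) -> ValidationReport:
    """Leave-one-out cross-validation bias of a sampling+estimation strategy.

    For each held-out population row a *fresh* sample is drawn from the
    remaining rows (one draw per point, as many times as ``n_passes``), the
    estimator is fit, and the held-out response predicted.

    Parameters
    ----------
    strategy
        One of ``srs``, ``strat_ignore``, ``ipb``.
    design
        Required for the stratified strategies.
    srs_n
        SRS sample size; defaults to the design's total sample size (so the
        strategies are compared at equal n) or is required when no design is
        given.
    n_iter
        IPB iterations per fit for coefficient estimators.
    inflation
        If set (and always for BRT), a single inflated IPB resample is used
        instead of iteration.
    holdout
        Evaluate only this many randomly chosen held-out points (or an
        explicit array of frame positions).  The full frame is the default;
        subsetting trades Monte-Carlo precision for runtime.
    n_passes
        Number of full passes over the held-out points; passes average down
        Monte-Carlo noise.
    max_skip_frac
        Points whose removal makes the design infeasible are skipped with a
        warning; exceeding this fraction aborts.

    Notes
    -----
    For the quantile family there is no per-point observed quantile to
    predict, so errors are measured against a reference surface: the same
    quantile model fit once to the full population.  This comparison is
    approximate by nature and is only used to compare strategies against
    each other.
    """
    rng = as_rng(rng)
    if strategy not in STRATEGIES:
        raise SchemaError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    sampler = None
    if strategy in ("strat_ignore", "ipb"):
        if design is None:
            raise SchemaError(f"strategy {strategy!r} requires a design")
        sampler = PreparedStratifiedSampler(frame, design)
        prob_by_pos = sampler.prob_by_position
        if srs_n is None:
            srs_n = sampler.n_sample
    else:
        if srs_n is None:
            raise SchemaError("strategy 'srs' requires srs_n")
        prob_by_pos = np.full(frame.n, srs_n / frame.n)
    if not (1 <= srs_n <= frame.n - 1):
        raise InvalidDesignError(f"sample size {srs_n} infeasible for LOO on {frame.n} rows")

    # reference surface for families without a per-point observed target
    if spec.family == "quantile":
        full = _srs_sample(frame, np.arange(frame.n), frame.n)
        ref_est = spec.fit(full)
        target = np.asarray(predict(ref_est, frame.covariates), dtype=float)
    else:
        target = frame.response

    if holdout is None:
        points = np.arange(frame.n)
    elif np.isscalar(holdout):
        points = rng.choice(frame.n, size=int(holdout), replace=False)
    else:
        points = np.asarray(holdout)

    rows = []
    n_skipped = 0
    for _ in range(n_passes):
        for i in points:
            try:
                pred = _loo_predict(
                    sampler, frame, strategy, spec, int(i), rng, srs_n, n_iter, inflation
                )
            except (InvalidDesignError, FailureBudgetExceeded) as exc:
                n_skipped += 1
                if n_skipped > max_skip_frac * len(points) * n_passes + 1:
                    raise FailureBudgetExceeded(
                        f"too many skipped LOO points ({n_skipped}): {exc}"
                    ) from exc
                warnings.warn(f"loo_bias: skipping point {i}: {exc}", stacklevel=2)
                continue
            rows.append((frame.unit_id[i], prob_by_pos[i], pred - target[i]))
    errors = pd.DataFrame(rows, columns=["unit_id", "inclusion_prob", "error"])
    if errors.empty:
        raise FailureBudgetExceeded("no LOO points could be evaluated")
    return ValidationReport(
        errors=errors,
        bias=float(errors["error"].mean()),
        error_sd=float(errors["error"].std(ddof=1)),
        prob_cov=probability_cov(prob_by_pos),
        strategy=strategy,
        family=spec.family,
        n_points=len(errors),
        n_skipped=n_skipped,
    )


def inclusion_frequency_experiment(
    frame: PopulationFrame,
    design: StratifiedDesign,
    n_reps: int,
    with_ipb: bool,
    rng,
    resample_size: int | None = None,
) -> pd.Series:
    """Empirical per-unit inclusion frequencies over replicate draws.

    For each replicate a stratified sample is drawn; with ``with_ipb`` the
    sample is additionally pushed through one IPB resample (equal size by
    default).  The returned frequency for a unit is its mean appearance
    count per replicate — for the without-replacement design stage the
    count is 0/1, so this is the ordinary inclusion frequency; for the
    with-replacement IPB stage multiplicities count, which is the accounting
    under which a design composed with IPB is uniform at ``n / N_pop``.
    """
    if n_reps < 1:
        raise SchemaError("n_reps must be >= 1")
    rng = as_rng(rng)
    sampler = PreparedStratifiedSampler(frame, design)
    counts = np.zeros(frame.n)
    size = sampler.n_sample if resample_size is None else resample_size
    if with_ipb:
        # weights depend only on the (fixed) stratum composition of the draw:
        # every drawn row from stratum h has P = n_h / N_h
        w = np.concatenate(
            [
                np.full(sampler.sizes[h], len(sampler.positions[h]) / sampler.sizes[h])
                for h in sampler.labels
            ]
        )
        w = w / w.sum()
        for _ in range(n_reps):
            idx = sampler.draw_positions(rng)
            take = rng.choice(len(idx), size=size, replace=True, p=w)
            np.add.at(counts, idx[take], 1.0)
    else:
        for _ in range(n_reps):
            counts[sampler.draw_positions(rng)] += 1.0
    return pd.Series(
        counts / n_reps, index=pd.Index(frame.unit_id, name="unit_id"), name="frequency"
    )


def scaled_stratification(
    base: StratificationSpec,
    frame: PopulationFrame,
    target_cov: float,
) -> StratificationSpec:
    """Rescale per-stratum probabilities to hit a target probability COV.

    The stratification structure is kept and the deviations of the stratum
    probabilities from their per-unit mean are scaled linearly:
    ``p_h(t) = p_bar + t (p_h - p_bar)``, which scales the COV by ``t``.
    ``target_cov = 0`` gives uniform probabilities (coincides with SRS up to
    size rounding).
    """
    if base.probs is None:
        raise SchemaError("COV scaling requires a probability-specified stratification")
    design = stratify_by_response(frame, base)
    per_unit = np.concatenate(
        [np.full(len(design.strata[h]), p) for h, p in zip(base.labels, base.probs)]
    )
    base_cov = probability_cov(per_unit)
    p_bar = per_unit.mean()
    t = target_cov / base_cov
    scaled = tuple(p_bar + t * (p - p_bar) for p in base.probs)
    if any(not (0.0 < p <= 1.0) for p in scaled):
        raise InvalidDesignError(
            f"target COV {target_cov} pushes a stratum probability outside (0,1]"
        )
    return StratificationSpec(
        cumulative_fractions=base.cumulative_fractions, probs=scaled, labels=base.labels
    )


def cov_sweep(
    frame: PopulationFrame,
    base: StratificationSpec,
    cov_grid,
    spec: EstimatorSpec,
    rng,
    strategies=("srs", "strat_ignore", "ipb"),
    n_iter: int = 50,
    inflation: float | None = None,
    holdout: int | None = None,
    reps: int = 1,
) -> pd.DataFrame:
    """Bias of each strategy across a grid of probability-COV levels.

    Per grid point the stratification's probabilities are rescaled with
    :func:`scaled_stratification`, a design is built, and
    :func:`loo_bias` is run per strategy.  Bias is reported both raw and as
    a percentage of the population response SD.  Infeasible grid points are
    skipped with a warning.
    """
    rng = as_rng(rng)
    sd_y = float(frame.response.std())
    out = []
    for cov in cov_grid:
        try:
            strat = scaled_stratification(base, frame, float(cov))
        except InvalidDesignError as exc:
            warnings.warn(f"cov_sweep: skipping COV={cov}: {exc}", stacklevel=2)
            continue
        design = stratify_by_response(frame, strat)
        for strategy in strategies:
            report = loo_bias(
                frame,
                strategy,
                spec,
                rng,
                design=design,
                n_iter=n_iter,
                inflation=inflation,
                holdout=holdout,
                n_passes=reps,
            )
            out.append(
                {
                    "prob_cov_target": float(cov),
                    "prob_cov": report.prob_cov,
                    "strategy": strategy,
                    "estimator": spec.family,
                    "bias": report.bias,
                    "bias_pct_of_sd": 100.0 * report.bias / sd_y,
                    "error_sd": report.error_sd,
                    "n_points": report.n_points,
                    "n_skipped": report.n_skipped,
                }
            )
    return pd.DataFrame(out)
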