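"""Inverse probability bootstrap: weights, resamples, and iterated runs.

The inverse probability bootstrap (IPB) transforms an unequal-probability
sample into equal-probability bootstrap samples.  Each row of the original
sample is resampled with replacement with probability proportional to the
inverse of its inclusion probability,

    w_i = (1 / P_i) / sum_j (1 / P_j),

so that, composed with the original design, every population unit has the
same chance of entering the resample.  Arbitrary model-based estimators can
then be fit to the resamples without violating their equal-probability
assumption; parameter estimates are averaged over iterations, and their
standard errors are the standard deviation across iterations, exactly as in
a conventional bootstrap.

For estimators that cannot meaningfully be averaged across fits (tree
ensembles, for instance) a single *inflated* resample of size
``inflation_factor * N`` is drawn instead.  Point estimates from an inflated
sample remain unbiased, but its apparent sample size overstates the
information content, so model-reported standard errors are invalid and the
sample is flagged accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FailureBudgetExceeded, SchemaError, SingularFitError
from .sampling import ProbabilitySample, as_rng

__all__ = [
    "IPBWeights",
    "IPBResult",
    "inverse_probability_weights",
    "ipb_resample",
    "inflated_ipb_sample",
    "run_ipb",
    "iteration_rng",
]

_WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class IPBWeights:
    """Normalized inverse-probability resampling weights for one sample.

    Invariants (checked at construction): the weights sum to one, every
    weight is positive, and ``w_i * P_i`` is constant across rows — i.e. the
    weights are exactly proportional to ``1 / P_i``.
    """

    weights: np.ndarray
    inclusion_prob: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        p = np.asarray(self.inclusion_prob, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "inclusion_prob", p)
        if w.ndim != 1 or w.shape != p.shape:
            raise SchemaError("weights and inclusion_prob must be aligned 1-d arrays")
        if (w <= 0).any():
            raise SchemaError("IPB weights must all be positive")
        if abs(w.sum() - 1.0) > _WEIGHT_TOL * max(1.0, len(w)):
            raise SchemaError(f"IPB weights sum to {w.sum()!r}, not 1")
        prod = w * p
        if np.ptp(prod) > _WEIGHT_TOL * max(1.0, prod.max()):
            raise SchemaError("IPB weights are not proportional to 1/P_i")

    @property
    def n(self) -> int:
        return len(self.weights)


def inverse_probability_weights(sample: ProbabilitySample) -> IPBWeights:
    """Compute normalized inverse-probability resampling weights.

    ``w_i = (1/P_i) / sum_j (1/P_j)``; a uniform-probability sample maps to
    uniform weights ``1/N``, so IPB then degenerates to the ordinary
    bootstrap.  The input sample is never mutated.
    """
    p = sample.inclusion_prob
    bad = ~np.isfinite(p) | (p <= 0)
    if bad.any():
        rows = np.flatnonzero(bad)[:5].tolist()
        raise SchemaError(
            f"cannot invert non-positive/non-finite inclusion probabilities; "
            f"offending rows (0-based): {rows}"
        )
    inv = 1.0 / p
    return IPBWeights(weights=inv / inv.sum(), inclusion_prob=p.copy())


def ipb_resample(
    sample: ProbabilitySample,
    weights: IPBWeights | None = None,
    size: int | None = None,
    rng=None,
) -> ProbabilitySample:
    """Draw one with-replacement IPB resample of the given size.

    Rows are drawn independently with probabilities ``w_i``; duplicates are
    expected and sampling *with replacement* is essential (without it the
    resample would simply reproduce the original sample).  Rows keep their
    original ``P_i`` for bookkeeping, but the resample is an
    equal-probability sample for all downstream purposes.
    """
    rng = as_rng(rng)
    if weights is None:
        weights = inverse_probability_weights(sample)
    if weights.n != sample.n:
        raise SchemaError("weights were not computed from this sample")
    if size is None:
        size = sample.n
    if size < 1:
        raise SchemaError(f"resample size must be >= 1, got {size}")
    idx = rng.choice(sample.n, size=size, replace=True, p=weights.weights)
    return sample.take(idx)


def inflated_ipb_sample(
    sample: ProbabilitySample,
    inflation_factor: float,
    rng=None,
) -> ProbabilitySample:
    """Single IPB resample of size ``round(inflation_factor * N)``.

    The result is flagged ``inflated`` so that model-reported standard
    errors, which scale with the square root of the apparent sample size, are
    suppressed downstream.  ``inflation_factor = 1`` is exactly
    :func:`ipb_resample` at the original size (flag aside).
    """
    if not np.isfinite(inflation_factor) or inflation_factor < 1.0:
        raise SchemaError(f"inflation factor must be finite and >= 1, got {inflation_factor}")
    size = int(round(inflation_factor * sample.n))
    out = ipb_resample(sample, size=size, rng=rng)
    out.inflated = inflation_factor > 1.0
    return out


def iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    """Per-iteration RNG stream: ``default_rng(SeedSequence([seed, iteration]))``.

    The counter-based scheme makes every iteration reproducible on its own,
    independent of execution order.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(iteration)]))


@dataclass
class IPBResult:
    """Aggregated output of an iterated (or single inflated) IPB run.

    ``mean_estimate`` is the coordinate-wise mean of the per-iteration
    estimates and ``se_estimate`` their standard deviation (the bootstrap
    standard error).  ``se_valid`` is False when only one iteration was run
    or when inflation was used, in which case ``se_estimate`` is withheld.
    """

    per_iteration: pd.DataFrame
    mean_estimate: pd.Series
    se_estimate: pd.Series | None
    n_iter: int
    n_failed: int
    inflation_factor: float
    seed: int
    se_valid: bool

    def recompute_mean(self) -> pd.Series:
        return self.per_iteration.mean(axis=0)


def run_ipb(
    sample: ProbabilitySample,
    estimator,
    n_iter: int = 1000,
    seed: int = 0,
    size: int | None = None,
    max_fail_frac: float = 0.05,
) -> IPBResult:
    """Iterate (IPB resample -> fit) cycles and aggregate named coefficients.

    Parameters
    ----------
    estimator
        An :class:`~ipboot.estimators.EstimatorSpec` (or any object with a
        ``fit_coefficients(sample) -> Mapping[str, float]`` method).  The
        estimator must emit *named* coefficients; aggregation is by name,
        not position.
    n_iter
        Number of bootstrap iterations (default 1000).
    seed
        Master seed; iteration ``i`` uses :func:`iteration_rng`.
    size
        Resample size (default: the original sample size ``N``).
    max_fail_frac
        Isolated estimator failures (singular fits on degenerate resamples)
        are dropped and counted; the run aborts if more than this fraction
        of iterations fail.

    Deterministic given (sample, estimator, n_iter, seed): repeated runs
    produce bit-identical recorded estimates.
    """
    if n_iter < 1:
        raise SchemaError(f"n_iter must be >= 1, got {n_iter}")
    weights = inverse_probability_weights(sample)
    records: list[dict] = []
    n_failed = 0
    for i in range(n_iter):
        rng = iteration_rng(seed, i)
        resample = ipb_resample(sample, weights=weights, size=size, rng=rng)
        try:
            coefs = estimator.fit_coefficients(resample)
        except SingularFitError:
            n_failed += 1
            continue
        records.append(dict(coefs))
    if n_failed > max_fail_frac * n_iter or not records:
        raise FailureBudgetExceeded(
            f"{n_failed}/{n_iter} IPB iterations failed to fit "
            f"(budget {max_fail_frac:.0%}); sample too degenerate for this estimator"
        )
    if n_failed:
        warnings.warn(
            f"run_ipb: dropped {n_failed}/{n_iter} failed iterations", stacklevel=2
        )
    per_iter = pd.DataFrame.from_records(records)
    mean = per_iter.mean(axis=0)
    ok = len(records) > 1
    se = per_iter.std(axis=0, ddof=1) if ok else None
    return IPBResult(
        per_iteration=per_iter,
        mean_estimate=mean,
        se_estimate=se,
        n_iter=n_iter,
        n_failed=n_failed,
        inflation_factor=1.0,
        seed=seed,
        se_valid=ok,
    )
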