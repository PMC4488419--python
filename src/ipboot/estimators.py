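"""Model-based estimators behind a uniform fit/predict contract.

Three families are provided, matching the model-based tools most often
applied to ecological survey data:

``ols``
    Ordinary least squares, solved by ``numpy.linalg.lstsq``.
``quantile``
    Linear quantile regression at level ``tau`` (default 0.95, the upper
    tail commonly used for carrying-capacity / limiting-factor questions),
    solved exactly as a linear program minimizing the check (pinball) loss
    ``sum_i rho_tau(y_i - x_i' beta)`` with HiGHS.  The solver returns a
    basic (vertex) solution; for an intercept-only fit with ``n * tau``
    integral this is the *lower* of the two optimal order statistics, which
    is the empirical-quantile convention this package pins.
``brt``
    Boosted regression trees: stagewise least-squares gradient boosting of
    depth-limited trees (scikit-learn's ``GradientBoostingRegressor``).

All three are deterministic given (data, hyperparameters, seed); the BRT's
row subsampling uses the explicit ``seed`` field.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .errors import SchemaError, SingularFitError
from .sampling import ProbabilitySample

__all__ = [
    "EstimatorSpec",
    "ParameterEstimate",
    "fit",
    "fit_ols",
    "fit_quantile",
    "fit_brt",
    "predict",
]

_FAMILIES = ("ols", "quantile", "brt")


@dataclass(frozen=True)
class EstimatorSpec:
    """Estimator family plus hyperparameters.

    BRT defaults (500 trees of depth 3, learning rate 0.05, 50% row
    subsampling) are deliberately conservative; they are configurable and
    none of the qualitative bias behaviour depends on them.
    """

    family: str = "ols"
    tau: float = 0.95
    n_trees: int = 500
    max_depth: int = 3
    learning_rate: float = 0.05
    subsample: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise SchemaError(f"unknown estimator family {self.family!r}")
        if self.family == "quantile" and not (0.0 < self.tau < 1.0):
            raise SchemaError(f"quantile level tau={self.tau} not in (0,1)")
        if self.family == "brt":
            if self.n_trees < 1 or self.max_depth < 1:
                raise SchemaError("brt: n_trees and max_depth must be >= 1")
            if not (0.0 < self.learning_rate <= 1.0):
                raise SchemaError("brt: learning rate must be in (0,1]")
            if not (0.0 < self.subsample <= 1.0):
                raise SchemaError("brt: subsample fraction must be in (0,1]")

    def with_seed(self, seed: int) -> "EstimatorSpec":
        return replace(self, seed=seed)

    # -- uniform contract used by run_ipb / validation ---------------------
    def fit(self, sample: ProbabilitySample) -> "ParameterEstimate":
        return fit(sample, self)

    def fit_coefficients(self, sample: ProbabilitySample) -> Mapping[str, float]:
        est = fit(sample, self)
        if est.coefficients is None:
            raise SchemaError(
                f"{self.family} does not emit named coefficients; iterate-and-average "
                "does not apply — use an inflated IPB sample instead"
            )
        return est.coefficients


@dataclass
class ParameterEstimate:
    """A fitted model: named coefficients (ols/quantile) or a tree ensemble.

    ``coefficients`` maps ``"intercept"`` plus each covariate name to a
    real; for BRT it is None and ``model`` holds the fitted ensemble.
    """

    family: str
    covariate_names: tuple[str, ...]
    coefficients: dict[str, float] | None = None
    model: object = None

    def coef_vector(self) -> np.ndarray:
        """(intercept, slopes...) in covariate order."""
        if self.coefficients is None:
            raise SchemaError("tree-ensemble estimates have no coefficient vector")
        return np.array(
            [self.coefficients["intercept"]]
            + [self.coefficients[c] for c in self.covariate_names]
        )


def _design_matrix(sample: ProbabilitySample) -> tuple[np.ndarray, np.ndarray]:
    X = np.column_stack([np.ones(sample.n), sample.covariates])
    return X, sample.response


def fit(sample: ProbabilitySample, spec: EstimatorSpec) -> ParameterEstimate:
    """Dispatch to the family-specific fitting routine."""
    if spec.family == "ols":
        return fit_ols(sample, spec)
    if spec.family == "quantile":
        return fit_quantile(sample, spec)
    return fit_brt(sample, spec)


def fit_ols(sample: ProbabilitySample, spec: EstimatorSpec | None = None) -> ParameterEstimate:
    """Least-squares fit of response on intercept + covariates.

    Equals the normal-equations solution; raises :class:`SingularFitError`
    on a rank-deficient design (e.g. a degenerate bootstrap resample made of
    duplicated rows), which the IPB driver's failure policy absorbs.
    """
    X, y = _design_matrix(sample)
    if X.shape[0] < X.shape[1]:
        raise SingularFitError(f"need more rows ({X.shape[0]}) than parameters ({X.shape[1]})")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise SingularFitError(f"design matrix rank {rank} < {X.shape[1]}")
    names = ["intercept", *sample.covariate_names]
    return ParameterEstimate(
        family="ols",
        covariate_names=sample.covariate_names,
        coefficients=dict(zip(names, beta.tolist())),
    )


def check_loss(tau: float, residuals: np.ndarray) -> float:
    """Pinball loss sum_i rho_tau(u_i), rho_tau(u) = u * (tau - 1{u<0})."""
    u = np.asarray(residuals, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


def fit_quantile(sample: ProbabilitySample, spec: EstimatorSpec) -> ParameterEstimate:
    """Linear quantile regression at level ``spec.tau`` via an exact LP.

    Decision variables are (beta, u, v) with ``X beta + u - v = y`` and
    ``u, v >= 0``; the objective ``tau * sum(u) + (1 - tau) * sum(v)`` equals
    the check loss at the optimum.
    """
    tau = spec.tau
    X, y = _design_matrix(sample)
    n, k = X.shape
    c = np.concatenate([np.zeros(k), np.full(n, tau), np.full(n, 1.0 - tau)])
    A_eq = np.hstack([X, np.eye(n), -np.eye(n)])
    bounds = [(None, None)] * k + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise SingularFitError(f"quantile LP failed: {res.message}")
    beta = res.x[:k]
    names = ["intercept", *sample.covariate_names]
    return ParameterEstimate(
        family="quantile",
        covariate_names=sample.covariate_names,
        coefficients=dict(zip(names, beta.tolist())),
    )


def fit_brt(sample: ProbabilitySample, spec: EstimatorSpec) -> ParameterEstimate:
    """Stagewise least-squares gradient boosting of depth-limited trees.

    A constant response yields a mean (intercept-only) predictor rather than
    an error.  Training loss is non-increasing per stage when
    ``subsample == 1``; stochastic subsampling uses ``spec.seed``.
    """
    from sklearn.ensemble import GradientBoostingRegressor

    if sample.n < 2:
        raise SingularFitError("brt needs at least 2 rows")
    y = sample.response
    if np.ptp(y) == 0.0:
        return ParameterEstimate(
            family="brt",
            covariate_names=sample.covariate_names,
            model=float(y[0]),  # constant predictor
        )
    model = GradientBoostingRegressor(
        n_estimators=spec.n_trees,
        max_depth=spec.max_depth,
        learning_rate=spec.learning_rate,
        subsample=spec.subsample,
        random_state=spec.seed,
    )
    model.fit(sample.covariates, y)
    return ParameterEstimate(
        family="brt", covariate_names=sample.covariate_names, model=model
    )


def predict(estimate: ParameterEstimate, covariates) -> np.ndarray:
    """Predict the response for one or more covariate rows.

    ``covariates`` may be a mapping {name: value}, a 1-d row in training
    order, or an ``(m, p)`` array.  Linear predictor for ols/quantile;
    ensemble sum for brt.
    """
    p = len(estimate.covariate_names)
    if isinstance(covariates, Mapping):
        missing = [c for c in estimate.covariate_names if c not in covariates]
        if missing:
            raise SchemaError(f"missing covariates in prediction row: {missing}")
        X = np.array([[float(covariates[c]) for c in estimate.covariate_names]])
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[1] != p:
            raise SchemaError(f"expected {p} covariates, got {X.shape[1]}")
    if estimate.family in ("ols", "quantile"):
        b = estimate.coef_vector()
        out = b[0] + X @ b[1:]
    elif isinstance(estimate.model, float):
        out = np.full(X.shape[0], estimate.model)
    else:
        out = estimate.model.predict(X)
    return np.asarray(out) if np.size(out) > 1 else float(np.ravel(out)[0])
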