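"""Synthetic ecological populations and the packaged study configurations.

Two ready-made configurations drive every reproduction pipeline:

``sim1``
    A 100-unit population in four strata of 25 (units 1-25 = A, 26-50 = B,
    51-75 = C, 76-100 = D) with per-stratum sample sizes (2, 3, 6, 9) —
    inclusion probabilities 0.08 / 0.12 / 0.24 / 0.36.  Used for the
    replicate inclusion-frequency experiments.

``sim2``
    A 1400-unit population of one response Y and six correlated covariates
    X1..X6 drawn from a multivariate normal with the study's mean vector and
    within-cluster variance-covariance matrix, plus an independent
    between-cluster dispersion on the covariates (see below).  Five strata
    A-E are cut along increasing Y at cumulative population shares
    31/44/57/67%, with per-unit inclusion probabilities
    0.71/0.36/0.18/0.18/0.14.

Cluster dispersion
------------------
Real ecological metrics are clustered: covariates carry between-cluster
heterogeneity on top of their within-cluster covariance.  The generator
models this as an additive, mutually independent mean offset per covariate
with diagonal variance ``D``.  ``D`` is not a free knob: it is derived in
closed form from the published population regression slopes ``beta*`` of Y
on X1..X6,

    D_j = (sigma_xy - Sigma_xx beta*)_j / beta*_j,

i.e. the unique diagonal inflation of the covariate covariance under which
the population slopes equal ``beta*``.  The response's own between-cluster
dispersion is unidentifiable from the slopes and is left at zero.  (The
entry for X5 is poorly determined because its slope is nearly zero; it only
inflates the variance of a covariate with negligible effect.)  By default
offsets are per-unit, which realizes the same population covariance as a
many-cluster geometry; an explicit ``n_clusters`` shares offsets within
clusters for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidDesignError, SchemaError
from .sampling import PopulationFrame, StratifiedDesign, as_rng

__all__ = [
    "PopulationSpec",
    "StratificationSpec",
    "generate_population",
    "stratify_by_response",
    "study_configs",
    "sim1_frame",
    "sim1_design",
    "sim2_population_spec",
    "sim2_stratification",
    "cluster_dispersion_from_slopes",
]

# --- sim2 constants --------------------------------------------------------

SIM2_VARIABLES = ("Y", "X1", "X2", "X3", "X4", "X5", "X6")

SIM2_MEAN = np.array([2.0, 4.0, 3.0, 2.0, 2.0, 3.0, 8.0])

SIM2_COVARIANCE = np.array(
    [
        [2.0, 0.9, 0.5, 3.0, 0.3, 0.0, 0.1],
        [0.9, 4.0, 0.0, 0.4, 0.0, 0.0, 0.5],
        [0.5, 0.0, 3.0, 0.0, 0.0, 0.0, 0.0],
        [3.0, 0.4, 0.0, 7.0, 2.0, 0.0, 2.0],
        [0.3, 0.0, 0.0, 2.0, 4.0, 0.0, 0.2],
        [0.0, 0.0, 0.0, 0.0, 0.0, 2.0, 1.0],
        [0.1, 0.5, 0.0, 2.0, 0.2, 1.0, 5.0],
    ]
)

# published population regression slopes of Y on X1..X6 for the sim2 data
SIM2_TRUE_SLOPES = np.array([0.098, 0.111, 0.436, -0.120, 0.008, -0.080])

SIM2_N_UNITS = 1400
# cumulative boundaries from the published stratum counts (435/183/182/143/457
# of 1400); the rounded percentage shares 31/44/57/67% are not precise enough
# to reproduce the counts to within one unit
SIM2_STRATUM_COUNTS = (435, 183, 182, 143, 457)
SIM2_STRATUM_FRACTIONS = (435 / 1400, 618 / 1400, 800 / 1400, 943 / 1400)
SIM2_STRATUM_PROBS = (0.71, 0.36, 0.18, 0.18, 0.14)

# --- sim1 constants --------------------------------------------------------

SIM1_N_UNITS = 100
SIM1_STRATUM_SIZES = {"A": 2, "B": 3, "C": 6, "D": 9}


def cluster_dispersion_from_slopes(
    covariance: np.ndarray = SIM2_COVARIANCE,
    target_slopes: np.ndarray = SIM2_TRUE_SLOPES,
) -> np.ndarray:
    """Diagonal covariate dispersion under which population slopes hit target.

    Solving ``(Sigma_xx + diag(D)) beta* = sigma_xy`` for diagonal ``D``
    gives ``D_j = (sigma_xy - Sigma_xx beta*)_j / beta*_j``.  Returns the
    length-7 diagonal (response entry 0).  Raises if any entry is negative,
    which would mean the target slopes are not reachable by independent
    covariate offsets.
    """
    Sxx = covariance[1:, 1:]
    sxy = covariance[1:, 0]
    beta = np.asarray(target_slopes, dtype=float)
    resid = sxy - Sxx @ beta
    D = resid / beta
    if (D < -1e-9).any():
        raise SchemaError("target slopes unreachable: implied dispersion negative")
    return np.concatenate([[0.0], np.clip(D, 0.0, None)])


@dataclass
class PopulationSpec:
    """Everything needed to draw one synthetic population."""

    n_units: int
    mean: np.ndarray
    covariance: np.ndarray
    variable_names: tuple[str, ...]
    cluster_dispersion: np.ndarray | None = None  # diagonal, same length as mean
    n_clusters: int | None = None  # None: per-unit offsets
    seed: int | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        k = len(self.mean)
        if self.covariance.shape != (k, k):
            raise SchemaError("covariance shape does not match mean vector")
        if not np.allclose(self.covariance, self.covariance.T):
            raise SchemaError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.covariance).min() < -1e-10:
            raise SchemaError("covariance must be positive semi-definite")
        if len(self.variable_names) != k:
            raise SchemaError("variable_names length mismatch")
        if self.cluster_dispersion is not None:
            self.cluster_dispersion = np.asarray(self.cluster_dispersion, dtype=float)
            if self.cluster_dispersion.shape != (k,) or (self.cluster_dispersion < 0).any():
                raise SchemaError("cluster_dispersion must be a nonnegative length-k diagonal")


@dataclass(frozen=True)
class StratificationSpec:
    """Response-quantile stratification with per-stratum design parameters."""

    cumulative_fractions: tuple[float, ...]  # strictly increasing, in (0,1)
    probs: tuple[float, ...] | None = None  # one per stratum (len fractions + 1)
    sizes: tuple[int, ...] | None = None
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        f = self.cumulative_fractions
        if any(not (0.0 < x < 1.0) for x in f) or any(
            b <= a for a, b in zip(f, f[1:])
        ):
            raise SchemaError("cumulative fractions must be strictly increasing in (0,1)")
        k = len(f) + 1
        if (self.probs is None) == (self.sizes is None):
            raise SchemaError("give exactly one of per-stratum probs or sizes")
        given = self.probs if self.probs is not None else self.sizes
        if len(given) != k:
            raise SchemaError(f"need {k} per-stratum values, got {len(given)}")
        if self.labels is None:
            object.__setattr__(
                self, "labels", tuple(chr(ord("A") + i) for i in range(k))
            )
        elif len(self.labels) != k:
            raise SchemaError("labels length mismatch")


def generate_population(spec: PopulationSpec, rng=None) -> PopulationFrame:
    """Draw a population frame from a (possibly clustered) multivariate normal.

    Sampling uses a fixed lower-Cholesky factorization and a fixed variable
    ordering so identical seeds give identical frames across platforms.  The
    first variable is the response; unit ids are 1-based labels.
    """
    rng = as_rng(spec.seed if rng is None else rng)
    k = len(spec.mean)
    n = spec.n_units
    if n < 1:
        raise SchemaError("n_units must be >= 1")
    if np.allclose(spec.covariance, 0.0):
        data = np.tile(spec.mean, (n, 1)).astype(float)
    else:
        # PSD-safe Cholesky: jitter only if strictly singular
        cov = spec.covariance
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            L = np.linalg.cholesky(cov + 1e-10 * np.eye(k))
        data = spec.mean + rng.standard_normal((n, k)) @ L.T
    if spec.cluster_dispersion is not None and spec.cluster_dispersion.any():
        sd = np.sqrt(spec.cluster_dispersion)
        if spec.n_clusters is None:
            offsets = rng.standard_normal((n, k)) * sd
        else:
            if spec.n_clusters < 1:
                raise SchemaError("n_clusters must be >= 1")
            centers = rng.standard_normal((spec.n_clusters, k)) * sd
            assign = rng.integers(0, spec.n_clusters, size=n)
            offsets = centers[assign]
        data = data + offsets
    return PopulationFrame(
        unit_id=np.arange(1, n + 1),
        response=data[:, 0],
        covariates=data[:, 1:],
        covariate_names=spec.variable_names[1:],
    )


def stratify_by_response(
    frame: PopulationFrame, strat: StratificationSpec
) -> StratifiedDesign:
    """Cut contiguous response-quantile strata and attach design parameters.

    Units are ranked by (response, unit_id) with a stable sort, so a unit
    exactly on a boundary value goes to the lower-labeled stratum,
    deterministically.  Stratum population shares match the cumulative
    fractions to within one unit (integer boundaries are ``round(f * N)``).
    """
    n = frame.n
    bounds = [int(round(f * n)) for f in strat.cumulative_fractions] + [n]
    if any(b <= a for a, b in zip([0] + bounds, bounds)):
        raise InvalidDesignError("fractions produce an empty stratum on this frame")
    order = np.lexsort((frame.unit_id, frame.response))
    strata: dict[str, np.ndarray] = {}
    lo = 0
    for label, hi in zip(strat.labels, bounds):
        strata[label] = np.sort(frame.unit_id[order[lo:hi]])
        lo = hi
    if strat.probs is not None:
        return StratifiedDesign(
            strata=strata, probs=dict(zip(strat.labels, strat.probs))
        )
    return StratifiedDesign(strata=strata, sizes=dict(zip(strat.labels, strat.sizes)))


# ---------------------------------------------------------------------------
# packaged configurations
# ---------------------------------------------------------------------------


def sim1_frame() -> PopulationFrame:
    """The 100-unit frame for the inclusion-frequency experiment.

    The experiment only tracks unit identities, so the response is a
    placeholder (the unit label) and there are no covariates.
    """
    ids = np.arange(1, SIM1_N_UNITS + 1)
    stratum = np.repeat(list(SIM1_STRATUM_SIZES), 25)
    return PopulationFrame(
        unit_id=ids,
        response=ids.astype(float),
        covariates=np.empty((SIM1_N_UNITS, 0)),
        covariate_names=(),
        stratum=stratum,
    )


def sim1_design() -> StratifiedDesign:
    """Four strata of 25 units with sample sizes (2, 3, 6, 9)."""
    strata = {
        label: np.arange(1 + 25 * i, 26 + 25 * i)
        for i, label in enumerate(SIM1_STRATUM_SIZES)
    }
    return StratifiedDesign(strata=strata, sizes=dict(SIM1_STRATUM_SIZES))


def sim2_population_spec(
    n_units: int = SIM2_N_UNITS,
    seed: int | None = None,
    clustered: bool = True,
) -> PopulationSpec:
    """Population spec for the correlated 7-variable ecological population.

    ``clustered=False`` drops the between-cluster covariate dispersion and
    draws a plain multivariate normal from the covariance table (useful for
    sensitivity analysis; the published population slopes are only realized
    with the dispersion in place).
    """
    return PopulationSpec(
        n_units=n_units,
        mean=SIM2_MEAN.copy(),
        covariance=SIM2_COVARIANCE.copy(),
        variable_names=SIM2_VARIABLES,
        cluster_dispersion=cluster_dispersion_from_slopes() if clustered else None,
        seed=seed,
    )


def sim2_stratification() -> StratificationSpec:
    """Five Y-quantile strata (31/13/13/10/33% shares) with the study probs."""
    return StratificationSpec(
        cumulative_fractions=SIM2_STRATUM_FRACTIONS,
        probs=SIM2_STRATUM_PROBS,
    )


def study_configs() -> dict:
    """Named, ready-made configuration bundles for the reproduction runs."""
    return {
        "sim1": {"frame": sim1_frame, "design": sim1_design},
        "sim2": {
            "population_spec": sim2_population_spec,
            "stratification": sim2_stratification,
        },
    }
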