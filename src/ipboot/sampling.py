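"""Finite populations, unequal-probability sampling designs, and sample draws.

A finite population is held in a :class:`PopulationFrame`; a survey design
(stratified with per-stratum sample sizes or per-unit inclusion probabilities,
or simple random sampling) yields a :class:`ProbabilitySample` in which every
row carries its inclusion probability ``P_i``.  The inclusion probability is
the probability that a given population unit enters the drawn sample, and it
is the single piece of design information every downstream operation needs.

All stochastic operations take an explicit :class:`numpy.random.Generator`
(or an integer seed); there is no hidden global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidDesignError, PartitionError, SchemaError

__all__ = [
    "PopulationFrame",
    "StratifiedDesign",
    "ProbabilitySample",
    "PreparedStratifiedSampler",
    "inclusion_probabilities",
    "draw_stratified_sample",
    "draw_srs",
    "probability_cov",
    "as_rng",
]


def as_rng(rng_or_seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence, or Generator into a Generator."""
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PopulationFrame:
    """A finite population: one row per unit, a response, named covariates.

    Parameters
    ----------
    unit_id
        Unique integer labels (1-based in all packaged fixtures).
    response
        Real-valued response per unit.
    covariates
        ``(n, p)`` array of covariate values; may have ``p == 0``.
    covariate_names
        Column names for ``covariates``.
    stratum
        Optional per-unit stratum labels.
    """

    unit_id: np.ndarray
    response: np.ndarray
    covariates: np.ndarray
    covariate_names: tuple[str, ...]
    stratum: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.unit_id = np.asarray(self.unit_id)
        self.response = np.asarray(self.response, dtype=float)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.size == 0:
            self.covariates = self.covariates.reshape(len(self.unit_id), 0)
        self.covariate_names = tuple(self.covariate_names)
        n = len(self.unit_id)
        if n < 1:
            raise SchemaError("population must contain at least one unit")
        if len(np.unique(self.unit_id)) != n:
            raise SchemaError("unit_id values must be unique")
        if self.response.shape != (n,):
            raise SchemaError("response must be one value per unit")
        if self.covariates.shape != (n, len(self.covariate_names)):
            raise SchemaError(
                f"covariates shape {self.covariates.shape} does not match "
                f"{n} units x {len(self.covariate_names)} names"
            )
        if self.stratum is not None:
            self.stratum = np.asarray(self.stratum)
            if self.stratum.shape != (n,):
                raise SchemaError("stratum must be one label per unit")

    @property
    def n(self) -> int:
        return len(self.unit_id)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        response: str = "response",
        unit_id: str = "unit_id",
        stratum: str = "stratum",
        covariates: Sequence[str] | None = None,
    ) -> "PopulationFrame":
        for col in (unit_id, response):
            if col not in df.columns:
                raise SchemaError(f"required column {col!r} missing")
        if covariates is None:
            reserved = {unit_id, response, stratum, "inclusion_prob"}
            covariates = [c for c in df.columns if c not in reserved]
        return cls(
            unit_id=df[unit_id].to_numpy(),
            response=df[response].to_numpy(dtype=float),
            covariates=df[list(covariates)].to_numpy(dtype=float),
            covariate_names=tuple(covariates),
            stratum=df[stratum].to_numpy() if stratum in df.columns else None,
        )

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame({"unit_id": self.unit_id, "response": self.response})
        for j, name in enumerate(self.covariate_names):
            out[name] = self.covariates[:, j]
        if self.stratum is not None:
            out["stratum"] = self.stratum
        return out


@dataclass(frozen=True)
class StratifiedDesign:
    """A stratified sampling design over an explicit partition of unit ids.

    Exactly one of ``sizes`` (per-stratum sample sizes, drawn without
    replacement) or ``probs`` (per-unit inclusion probabilities, realized as
    fixed sizes ``n_h = round(p_h * N_h)``) is given per design.
    """

    strata: Mapping[str, np.ndarray]  # label -> array of unit ids
    sizes: Mapping[str, int] | None = None
    probs: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "strata", {k: np.asarray(v) for k, v in self.strata.items()}
        )
        if (self.sizes is None) == (self.probs is None):
            raise InvalidDesignError("give exactly one of per-stratum sizes or probs")
        if self.probs is not None:
            for h, p in self.probs.items():
                if not (0.0 < p <= 1.0):
                    raise InvalidDesignError(f"stratum {h!r}: probability {p} not in (0,1]")
        if self.sizes is not None:
            for h, n in self.sizes.items():
                if n < 0:
                    raise InvalidDesignError(f"stratum {h!r}: negative sample size")

    @property
    def labels(self) -> list[str]:
        return list(self.strata.keys())

    def stratum_sizes(self) -> dict[str, int]:
        return {h: len(ids) for h, ids in self.strata.items()}

    def sample_sizes(self) -> dict[str, int]:
        """Realized per-stratum sample sizes n_h."""
        if self.sizes is not None:
            return dict(self.sizes)
        assert self.probs is not None
        return {
            h: int(round(self.probs[h] * len(ids))) for h, ids in self.strata.items()
        }

    def validate(self, frame: PopulationFrame) -> None:
        """Check the strata partition the frame and sizes are feasible."""
        all_ids = np.concatenate([ids for ids in self.strata.values()])
        if len(all_ids) != len(np.unique(all_ids)):
            raise PartitionError("a unit appears in more than one stratum")
        frame_ids = np.sort(frame.unit_id)
        if len(all_ids) != frame.n or not np.array_equal(np.sort(all_ids), frame_ids):
            raise PartitionError("design strata do not partition the population frame")
        for h, n_h in self.sample_sizes().items():
            N_h = len(self.strata[h])
            if n_h > N_h:
                raise InvalidDesignError(
                    f"stratum {h!r}: sample size {n_h} exceeds stratum size {N_h}"
                )


@dataclass
class ProbabilitySample:
    """A drawn sample; every row carries its inclusion probability ``P_i``.

    ``inflated`` marks samples produced by inflated resampling, whose apparent
    size exceeds the information content of the underlying draw; standard
    errors computed from such samples are invalid and are suppressed
    downstream.
    """

    unit_id: np.ndarray
    response: np.ndarray
    covariates: np.ndarray
    covariate_names: tuple[str, ...]
    inclusion_prob: np.ndarray
    stratum: np.ndarray | None = None
    inflated: bool = False

    def __post_init__(self) -> None:
        self.unit_id = np.asarray(self.unit_id)
        self.response = np.asarray(self.response, dtype=float)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.size == 0:
            self.covariates = self.covariates.reshape(len(self.unit_id), 0)
        self.inclusion_prob = np.asarray(self.inclusion_prob, dtype=float)
        self.covariate_names = tuple(self.covariate_names)
        n = len(self.unit_id)
        if n < 1:
            raise SchemaError("sample must contain at least one row")
        p = self.inclusion_prob
        if p.shape != (n,):
            raise SchemaError("inclusion_prob must be one value per row")
        bad = ~np.isfinite(p) | (p <= 0.0) | (p > 1.0)
        if bad.any():
            rows = np.flatnonzero(bad)[:5].tolist()
            raise SchemaError(
                f"inclusion probabilities must be finite and in (0,1]; "
                f"offending rows (0-based): {rows}"
            )

    @property
    def n(self) -> int:
        return len(self.unit_id)

    def take(self, idx: np.ndarray, inflated: bool | None = None) -> "ProbabilitySample":
        """Materialize a row subset/multiset (used by the bootstrap stage)."""
        return ProbabilitySample(
            unit_id=self.unit_id[idx],
            response=self.response[idx],
            covariates=self.covariates[idx],
            covariate_names=self.covariate_names,
            inclusion_prob=self.inclusion_prob[idx],
            stratum=None if self.stratum is None else self.stratum[idx],
            inflated=self.inflated if inflated is None else inflated,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        prob: str = "inclusion_prob",
        response: str = "response",
        unit_id: str = "unit_id",
        stratum: str = "stratum",
        covariates: Sequence[str] | None = None,
    ) -> "ProbabilitySample":
        for col in (unit_id, response, prob):
            if col not in df.columns:
                raise SchemaError(f"required column {col!r} missing")
        if covariates is None:
            reserved = {unit_id, response, stratum, prob}
            covariates = [c for c in df.columns if c not in reserved]
        return cls(
            unit_id=df[unit_id].to_numpy(),
            response=df[response].to_numpy(dtype=float),
            covariates=df[list(covariates)].to_numpy(dtype=float),
            covariate_names=tuple(covariates),
            inclusion_prob=df[prob].to_numpy(dtype=float),
            stratum=df[stratum].to_numpy() if stratum in df.columns else None,
        )

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame({"unit_id": self.unit_id, "response": self.response})
        for j, name in enumerate(self.covariate_names):
            out[name] = self.covariates[:, j]
        out["inclusion_prob"] = self.inclusion_prob
        if self.stratum is not None:
            out["stratum"] = self.stratum
        return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def inclusion_probabilities(
    frame: PopulationFrame, design: StratifiedDesign
) -> pd.Series:
    """Per-unit inclusion probabilities implied by a stratified design.

    For sample-size designs ``P_i = n_h / N_h`` for every unit in stratum h;
    for probability designs the realized probability ``n_h / N_h`` with
    ``n_h = round(p_h * N_h)`` is reported, so that replicate-frequency
    checks against the returned values are exact.

    Returns a :class:`pandas.Series` indexed by ``unit_id``.
    """
    design.validate(frame)
    sizes = design.sample_sizes()
    out = pd.Series(np.nan, index=pd.Index(frame.unit_id, name="unit_id"), name="P_i")
    for h, ids in design.strata.items():
        N_h = len(ids)
        p = sizes[h] / N_h
        if not (0.0 < p <= 1.0):
            raise InvalidDesignError(
                f"stratum {h!r}: realized probability {p} not in (0,1]"
            )
        out.loc[ids] = p
    return out


def _positions(frame: PopulationFrame, design: StratifiedDesign) -> dict[str, np.ndarray]:
    """Map each stratum's unit ids to 0-based row positions in the frame."""
    lookup = pd.Series(np.arange(frame.n), index=frame.unit_id)
    pos = {}
    for h, ids in design.strata.items():
        try:
            pos[h] = lookup.loc[ids].to_numpy()
        except KeyError as exc:  # unit id in design but not in frame
            raise PartitionError(f"stratum {h!r} references units absent from frame") from exc
    return pos


class PreparedStratifiedSampler:
    """A design bound to a frame, validated once, for repeated cheap draws.

    Replicate experiments and leave-one-out loops draw from the same design
    many thousands of times; this hoists validation, unit-id -> position
    lookup, and the per-unit probability vector out of the draw loop.
    :func:`draw_stratified_sample` is a one-shot wrapper around it.
    """

    def __init__(self, frame: PopulationFrame, design: StratifiedDesign):
        design.validate(frame)
        self.frame = frame
        self.design = design
        self.prob_by_position = inclusion_probabilities(frame, design).to_numpy()
        pos = _positions(frame, design)
        sizes = design.sample_sizes()
        self.labels = [h for h in design.labels if sizes[h] > 0]
        for h in self.labels:
            if len(pos[h]) == 0:
                raise InvalidDesignError(f"stratum {h!r} is empty but n_h={sizes[h]}")
        self.positions = {h: pos[h] for h in self.labels}
        self.sizes = {h: sizes[h] for h in self.labels}
        self.n_sample = sum(self.sizes.values())
        self.stratum_labels = np.concatenate(
            [np.repeat(h, self.sizes[h]) for h in self.labels]
        )
        # stratum index per frame position (-1: unit in a size-0 stratum)
        self.stratum_of_position = np.full(frame.n, -1)
        for j, h in enumerate(self.labels):
            self.stratum_of_position[self.positions[h]] = j

    def draw_positions(self, rng, exclude: int | None = None) -> np.ndarray:
        """Frame positions of one stratified draw, optionally excluding one unit.

        Exclusion supports leave-one-out validation: the excluded unit's
        stratum is sampled from its remaining members.  Raises
        InvalidDesignError if that exhausts the stratum.
        """
        chosen = []
        for j, h in enumerate(self.labels):
            p = self.positions[h]
            n_h = self.sizes[h]
            if exclude is not None and self.stratum_of_position[exclude] == j:
                p = p[p != exclude]
                if n_h > len(p):
                    raise InvalidDesignError(
                        f"stratum {h!r} exhausted after excluding unit at position {exclude}"
                    )
            chosen.append(rng.choice(p, size=n_h, replace=False))
        return np.concatenate(chosen)

    def sample_from_positions(self, idx: np.ndarray) -> ProbabilitySample:
        frame = self.frame
        return ProbabilitySample(
            unit_id=frame.unit_id[idx],
            response=frame.response[idx],
            covariates=frame.covariates[idx],
            covariate_names=frame.covariate_names,
            inclusion_prob=self.prob_by_position[idx],
            stratum=self.stratum_labels.copy(),
        )

    def draw(self, rng, exclude: int | None = None) -> ProbabilitySample:
        return self.sample_from_positions(self.draw_positions(as_rng(rng), exclude))


def draw_stratified_sample(
    frame: PopulationFrame,
    design: StratifiedDesign,
    rng,
) -> ProbabilitySample:
    """Draw a without-replacement stratified sample and attach P_i per row.

    Within each stratum exactly ``n_h`` distinct units are drawn uniformly at
    random.  Rows are ordered by stratum (design label order) so the stratum
    composition of the returned sample is deterministic even though the unit
    identities are random.
    """
    return PreparedStratifiedSampler(frame, design).draw(as_rng(rng))


def draw_srs(frame: PopulationFrame, n: int, rng) -> ProbabilitySample:
    """Simple random sample without replacement; every row gets P_i = n/N."""
    rng = as_rng(rng)
    if not (1 <= n <= frame.n):
        raise InvalidDesignError(f"sample size {n} not in [1, {frame.n}]")
    idx = rng.choice(frame.n, size=n, replace=False)
    return ProbabilitySample(
        unit_id=frame.unit_id[idx],
        response=frame.response[idx],
        covariates=frame.covariates[idx],
        covariate_names=frame.covariate_names,
        inclusion_prob=np.full(n, n / frame.n),
        stratum=None if frame.stratum is None else frame.stratum[idx],
    )


def probability_cov(probs) -> float:
    """Coefficient of variation of per-unit inclusion probabilities.

    Defined as the population standard deviation of the ``P_i`` divided by
    their mean: 0 for an equal-probability design, larger as the design
    departs further from uniform sampling.  Scale-invariant.
    """
    p = np.asarray(probs, dtype=float).ravel()
    if p.size == 0:
        raise SchemaError("probability_cov: empty probability vector")
    if not np.isfinite(p).all() or (p <= 0).any():
        raise SchemaError("probability_cov: probabilities must be finite and > 0")
    return float(p.std() / p.mean())
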