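"""CSV / YAML / JSON input and output.

CSV dialect: comma-separated, header required, UTF-8, "." decimal, no index
column.  Population and sample files need ``unit_id`` and ``response``
columns; a sample file additionally needs an inclusion-probability column
(default ``inclusion_prob``) unless a design config supplies one.  All other
numeric columns are treated as covariates.

Design configs are YAML with either explicit unit lists or a
response-quantile rule, e.g.::

    strata:
      - {label: A, units: [1, 2, 3], n: 2}
      - {label: B, units: [4, 5, 6], prob: 0.5}

    # or
    stratify_by_response:
      cumulative_fractions: [0.31, 0.44, 0.57, 0.67]
      probs: [0.71, 0.36, 0.18, 0.18, 0.14]

Every result artifact embeds the package version and the seed it was
produced with; reading a result back reproduces all numeric fields to full
precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import IPBResult
from .errors import SchemaError
from .population import StratificationSpec, stratify_by_response
from .sampling import PopulationFrame, ProbabilitySample, StratifiedDesign
from .validation import ValidationReport

__all__ = [
    "read_population_csv",
    "read_sample_csv",
    "read_design_config",
    "write_result",
    "read_result",
]


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def read_population_csv(path, **bindings) -> PopulationFrame:
    """Read a population frame; see :meth:`PopulationFrame.from_dataframe`."""
    return PopulationFrame.from_dataframe(_read_csv(path), **bindings)


def read_sample_csv(
    path,
    prob: str = "inclusion_prob",
    design: StratifiedDesign | None = None,
    **bindings,
) -> ProbabilitySample:
    """Read a probability sample, validating probabilities in (0,1].

    If the probability column is absent a design must be supplied; per-unit
    probabilities are then attached from the design.
    """
    df = _read_csv(path)
    if prob not in df.columns:
        if design is None:
            raise SchemaError(
                f"{path}: column {prob!r} missing and no design config supplied"
            )
        # probabilities only defined for units present in some stratum
        p = pd.Series(index=df["unit_id"], dtype=float)
        for h, ids in design.strata.items():
            n_h = design.sample_sizes()[h]
            p.loc[p.index.intersection(ids)] = n_h / len(ids)
        if p.isna().any():
            raise SchemaError(f"{path}: some units belong to no design stratum")
        df = df.assign(**{prob: p.to_numpy()})
    bad = df.index[
        ~np.isfinite(df[prob]) | (df[prob] <= 0) | (df[prob] > 1)
    ].tolist()
    if bad:
        raise SchemaError(
            f"{path}: invalid inclusion probability in data row(s) {bad[:5]} "
            "(must be in (0,1])"
        )
    return ProbabilitySample.from_dataframe(df, prob=prob, **bindings)


def read_design_config(path) -> StratifiedDesign | StratificationSpec:
    """Parse a YAML design config.

    Returns a :class:`StratifiedDesign` for explicit-unit configs, or a
    :class:`StratificationSpec` for response-quantile rules (bind it to a
    frame with :func:`ipboot.population.stratify_by_response`).
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: design config must be a mapping")
    if "stratify_by_response" in cfg:
        rule = cfg["stratify_by_response"]
        return StratificationSpec(
            cumulative_fractions=tuple(rule["cumulative_fractions"]),
            probs=tuple(rule["probs"]) if "probs" in rule else None,
            sizes=tuple(rule["sizes"]) if "sizes" in rule else None,
            labels=tuple(rule["labels"]) if "labels" in rule else None,
        )
    if "strata" not in cfg:
        raise SchemaError(f"{path}: need 'strata' or 'stratify_by_response'")
    strata, sizes, probs = {}, {}, {}
    for entry in cfg["strata"]:
        label = str(entry["label"])
        strata[label] = np.asarray(entry["units"])
        if "n" in entry:
            sizes[label] = int(entry["n"])
        if "prob" in entry:
            probs[label] = float(entry["prob"])
    if sizes and probs:
        raise SchemaError(f"{path}: mix of 'n' and 'prob' across strata")
    return StratifiedDesign(
        strata=strata, sizes=sizes or None, probs=probs or None
    )


def write_result(result, path, seed: int | None = None) -> None:
    """Serialize an IPBResult (JSON) or ValidationReport (JSON + errors CSV).

    Standard errors of an inflated run are flagged invalid and omitted from
    the serialized estimate block.  Round-trip: :func:`read_result` restores
    every numeric field to full precision.
    """
    path = Path(path)
    if isinstance(result, IPBResult):
        payload = {
            "kind": "ipb_result",
            "version": __version__,
            "seed": result.seed,
            "n_iter": result.n_iter,
            "n_failed": result.n_failed,
            "inflation_factor": result.inflation_factor,
            "se_valid": result.se_valid,
            "mean_estimate": result.mean_estimate.to_dict(),
            "se_estimate": result.se_estimate.to_dict() if result.se_valid else None,
            "per_iteration": result.per_iteration.to_dict(orient="list"),
        }
    elif isinstance(result, ValidationReport):
        payload = {
            "kind": "validation_report",
            "version": __version__,
            "seed": seed,
            "strategy": result.strategy,
            "estimator": result.family,
            "bias": result.bias,
            "error_sd": result.error_sd,
            "prob_cov": result.prob_cov,
            "n_points": result.n_points,
            "n_skipped": result.n_skipped,
            "errors": result.errors.to_dict(orient="list"),
        }
    else:
        raise SchemaError(f"cannot serialize {type(result).__name__}")
    try:
        path.write_text(json.dumps(payload, indent=1, default=float))
    except OSError as exc:
        raise SchemaError(f"cannot write result to {path}: {exc}") from exc


def read_result(path):
    """Inverse of :func:`write_result`."""
    payload = json.loads(Path(path).read_text())
    if payload.get("kind") == "ipb_result":
        per_iter = pd.DataFrame(payload["per_iteration"])
        se = payload["se_estimate"]
        return IPBResult(
            per_iteration=per_iter,
            mean_estimate=pd.Series(payload["mean_estimate"]),
            se_estimate=None if se is None else pd.Series(se),
            n_iter=payload["n_iter"],
            n_failed=payload["n_failed"],
            inflation_factor=payload["inflation_factor"],
            seed=payload["seed"],
            se_valid=payload["se_valid"],
        )
    if payload.get("kind") == "validation_report":
        errors = pd.DataFrame(payload["errors"])
        return ValidationReport(
            errors=errors,
            bias=payload["bias"],
            error_sd=payload["error_sd"],
            prob_cov=payload["prob_cov"],
            strategy=payload["strategy"],
            family=payload["estimator"],
            n_points=payload["n_points"],
            n_skipped=payload["n_skipped"],
        )
    raise SchemaError(f"{path}: unrecognized result file")
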