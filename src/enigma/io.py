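"""Readers and writers for count tables, metadata and result artifacts.

TSV is the canonical interchange format (CSV accepted by extension).  Count
tables may arrive samples-in-rows or taxa-in-rows (transposed at read time via
``orientation``), and relative-abundance tables are converted to pseudo-counts
by a multiplier (conventionally 10,000) followed by half-up rounding.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CovariateTable, OtuTable

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

__all__ = [
    "read_count_table",
    "read_metadata",
    "write_fit_result",
    "write_comparison",
    "write_selection",
    "write_simulation_metrics",
]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate row or column identifiers")
    return df


def read_count_table(path, orientation: str = "samples", scale: float = None) -> OtuTable:
    """Read a count (or relative-abundance) table into an :class:`OtuTable`.

    ``orientation="samples"`` expects samples in rows; ``"taxa"`` transposes a
    taxa-in-rows file.  With ``scale`` set, the body is multiplied by it and
    rounded half-up — the conventional route from relative abundances to
    pseudo-counts (multiplier 10,000).
    """
    if orientation not in ("samples", "taxa"):
        raise ValueError("orientation must be 'samples' or 'taxa'")
    df = _read_table(path)
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        bad = body.isna().stack()
        row, col = bad[bad].index[0]
        raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    if orientation == "taxa":
        body = body.T
    values = body.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError(f"{path}: negative values are not valid counts")
    if scale is not None:
        if scale <= 0:
            raise ValueError("scale must be positive")
        values = np.floor(values * float(scale) + 0.5)  # half-up rounding
    return OtuTable(
        counts=values,
        sample_ids=tuple(map(str, body.index)),
        taxon_ids=tuple(map(str, body.columns)),
    )


def read_metadata(path, covariate_columns, sample_ids) -> CovariateTable:
    """Read binary host-property columns aligned to the count-table samples.

    Columns already coded 0/1 pass through; two-level columns are encoded
    with the lexicographically smaller level as 0 (logged).  Columns with more
    than two levels are rejected — the model's covariates are binary.  Samples
    missing from the metadata raise an error naming them.
    """
    df = _read_table(path)
    df.index = df.index.map(str)
    sample_ids = [str(s) for s in sample_ids]
    missing = [s for s in sample_ids if s not in df.index]
    if missing:
        raise ValueError(f"{path}: samples missing from metadata: {missing}")
    df = df.loc[sample_ids]
    columns = []
    for name in covariate_columns:
        if name not in df.columns:
            raise ValueError(f"{path}: covariate column {name!r} not found")
        col = df[name]
        numeric = pd.to_numeric(col, errors="coerce")
        if numeric.notna().all() and set(numeric.unique()) <= {0.0, 1.0}:
            columns.append(numeric.to_numpy(dtype=float))
            continue
        levels = sorted(map(str, col.astype(str).unique()))
        if len(levels) != 2:
            raise ValueError(
                f"{path}: column {name!r} has {len(levels)} levels; binary expected"
            )
        logger.info("encoding %r: %s=0, %s=1", name, levels[0], levels[1])
        columns.append((col.astype(str) == levels[1]).to_numpy(dtype=float))
    return CovariateTable(
        design=np.column_stack(columns) if columns else np.zeros((len(sample_ids), 0)),
        covariate_names=tuple(covariate_columns),
        sample_ids=tuple(sample_ids),
    )


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dump_json(payload: dict, path: Path):
    payload = {"schema_version": SCHEMA_VERSION, **payload}
    path.write_text(json.dumps(payload, indent=2, default=_json_default, sort_keys=True) + "\n")


def write_fit_result(fit, Y: OtuTable, outdir, level: float = 0.95):
    """Serialize a fit: summary JSON, coefficient/interval TSV, responsibilities TSV."""
    from .inference import credible_intervals

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _dump_json(
        {
            "n_classes": fit.params.n_classes,
            "pi": fit.params.pi,
            "log_posterior": fit.log_posterior,
            "log_likelihood": fit.log_likelihood,
            "converged": bool(fit.converged),
            "grad_norm": fit.grad_norm,
            "n_free_parameters": fit.n_free_parameters,
            "n_restarts_used": fit.n_restarts_used,
            "seed": fit.seed,
        },
        outdir / "fit.json",
    )
    targets = ("B", "gamma", "class_occurrence") if fit.layout.M else ("gamma", "class_occurrence")
    ci = credible_intervals(fit, level=level, targets=targets)
    taxa = list(Y.taxon_ids)
    ci["taxon"] = [taxa[k] for k in ci["taxon"]]
    ci.to_csv(outdir / "coefficients.tsv", sep="\t", index=False, float_format="%.12g")
    resp = pd.DataFrame(
        fit.responsibilities,
        index=list(Y.sample_ids),
        columns=[f"class{l + 1}" for l in range(fit.params.n_classes)],
    )
    resp["assignment"] = fit.assignments + 1
    resp.to_csv(outdir / "responsibilities.tsv", sep="\t", float_format="%.12g")


def write_comparison(comparison, path):
    _dump_json(
        {
            "log_evidence_m1": comparison.log_evidence_m1,
            "log_evidence_m0": comparison.log_evidence_m0,
            "d_m1": comparison.d_m1,
            "d_m0": comparison.d_m0,
            "preferred": comparison.preferred,
        },
        Path(path),
    )


def write_selection(selection, path):
    _dump_json(
        {
            "candidate_L": list(selection.candidate_L),
            "ch_values": list(selection.ch_values),
            "chosen_L": selection.chosen_L,
            "degenerate": list(selection.degenerate),
        },
        Path(path),
    )


def write_simulation_metrics(metrics, outdir):
    """Per-coefficient TSV plus a JSON summary of a replicated study."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics.to_dataframe().to_csv(
        outdir / "simulation_metrics.tsv", sep="\t", index=False, float_format="%.6g"
    )
    _dump_json(
        {
            "mean_accuracy": metrics.mean_accuracy,
            "median_coverage": float(np.median(metrics.coverage)),
            "n_replicates_used": metrics.n_replicates_used,
            "n_failed": metrics.n_failed,
        },
        outdir / "simulation_summary.json",
    )
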