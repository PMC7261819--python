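"""Readers and writers for the TSV formats and the YAML run configuration.

All tabular I/O is tab-separated text with a single header line, "." as
the decimal mark and no thousands separators, matching common
search-engine exports.

Column conventions (documented here because search engines disagree on
naming):

quant table
    ``feature_id`` (PSM/peptide identifier), ``protein_id``, optional
    ``batch``, and one column per sample with raw linear-scale
    intensities. ``0``, ``NA`` and empty cells are missing values.

protein matrix
    ``protein_id``, ``count``, and one column per sample with log2
    relative abundances. Optional per-batch count columns are named
    ``count:<batch>``.

design
    ``sample``, ``group``, optional ``batch``, optional ``is_reference``
    (1/0, TRUE/FALSE).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    DesignSpec,
    ProteinMatrix,
    QuantTable,
    RunConfig,
    ValidationError,
)
from .ebayes import EBayesFit

__all__ = [
    "FormatSpec",
    "read_quant_table",
    "read_protein_matrix",
    "write_protein_matrix",
    "read_design",
    "write_results",
    "load_config",
]

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"NA", "NaN", "nan", ""}


@dataclass
class FormatSpec:
    """Column-naming convention of a quant table."""

    feature_col: str = "feature_id"
    protein_col: str = "protein_id"
    batch_col: str = "batch"
    sample_cols: list[str] | None = None  # None: all remaining columns


def _parse_intensity_block(
    raw: pd.DataFrame, sample_cols: list[str], path: str
) -> pd.DataFrame:
    block = pd.DataFrame(index=raw.index)
    for col in sample_cols:
        s = raw[col].astype(str).str.strip()
        missing = s.isin(_MISSING_TOKENS)
        parsed = pd.to_numeric(s.where(~missing), errors="coerce")
        bad = parsed.isna() & ~missing
        if bad.any():
            row = int(raw.index[bad][0])
            raise ValidationError(
                f"{path}: non-numeric intensity in column {col!r}, row {row + 2} "
                f"(value {raw[col].iloc[int(np.flatnonzero(bad)[0])]!r})"
            )
        n_missing = int(missing.sum())
        if n_missing:
            logger.info("%s: %d missing cells in column %s", path, n_missing, col)
        # zero intensities are "not observed", not zero abundance
        block[col] = parsed.mask(parsed == 0)
    return block


def read_quant_table(path: str | Path, format_spec: FormatSpec | None = None) -> QuantTable:
    """Read a PSM/peptide-level quant table (TSV)."""
    spec = format_spec or FormatSpec()
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (spec.feature_col, spec.protein_col):
        if col not in raw.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    reserved = {spec.feature_col, spec.protein_col, spec.batch_col}
    sample_cols = spec.sample_cols or [c for c in raw.columns if c not in reserved]
    missing_cols = [c for c in sample_cols if c not in raw.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing intensity columns {missing_cols}")
    if not sample_cols:
        raise ValidationError(f"{path}: no intensity columns found")

    data = pd.DataFrame(
        {
            "feature_id": raw[spec.feature_col],
            "protein_id": raw[spec.protein_col],
        }
    )
    if spec.batch_col in raw.columns:
        data["batch"] = raw[spec.batch_col]
    data = pd.concat([data, _parse_intensity_block(raw, sample_cols, str(path))], axis=1)
    return QuantTable(data=data, sample_ids=sample_cols)


def read_protein_matrix(path: str | Path) -> ProteinMatrix:
    """Read a proteins x samples log2 matrix; incomplete rows are dropped."""
    raw = pd.read_csv(path, sep="\t")
    for col in ("protein_id", "count"):
        if col not in raw.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    if raw["protein_id"].duplicated().any():
        dups = raw.loc[raw["protein_id"].duplicated(), "protein_id"].unique().tolist()
        raise ValidationError(f"{path}: duplicate protein ids: {dups}")
    raw = raw.set_index("protein_id")
    batch_cols = [c for c in raw.columns if c.startswith("count:")]
    sample_cols = [c for c in raw.columns if c != "count" and c not in batch_cols]
    values = raw[sample_cols].astype(float)
    complete = values.notna().all(axis=1)
    n_drop = int((~complete).sum())
    if n_drop:
        logger.info("%s: dropped %d proteins with missing values", path, n_drop)
    values = values[complete]
    count = raw.loc[complete, "count"]
    if (count < 1).any():
        raise ValidationError(f"{path}: counts must be >= 1")
    per_batch = None
    if batch_cols:
        per_batch = raw.loc[complete, batch_cols]
        per_batch.columns = [c.split(":", 1)[1] for c in batch_cols]
    return ProteinMatrix(values=values, count=count, per_batch_count=per_batch)


def write_protein_matrix(matrix: ProteinMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.insert(0, "count", matrix.count)
    if matrix.per_batch_count is not None:
        for b in matrix.per_batch_count.columns:
            out.insert(1, f"count:{b}", matrix.per_batch_count[b])
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_design(path: str | Path) -> DesignSpec:
    """Read a sample design TSV (columns: sample, group[, batch, is_reference])."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample", "group"):
        if col not in raw.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    sample_to_group = dict(zip(raw["sample"], raw["group"]))
    if len(sample_to_group) != len(raw):
        raise ValidationError(f"{path}: duplicate sample ids")
    batches = None
    if "batch" in raw.columns and raw["batch"].str.len().gt(0).any():
        batches = dict(zip(raw["sample"], raw["batch"]))
    refs: frozenset[str] = frozenset()
    if "is_reference" in raw.columns:
        truthy = raw["is_reference"].str.upper().isin({"1", "TRUE", "T", "YES"})
        refs = frozenset(raw.loc[truthy, "sample"])
    return DesignSpec(
        sample_to_group=sample_to_group, batches=batches, reference_samples=refs
    )


_RESULT_COLUMNS = [
    "protein_id",
    "count",
    "contrast",
    "log2FC",
    "t_ord",
    "p_ord",
    "t_mod",
    "p_mod",
    "q_mod",
    "pooled_var",
    "prior_var",
    "post_var",
    "resid_df",
    "prior_df",
]


def write_results(fit: EBayesFit, path: str | Path) -> None:
    """Write the per-contrast moderated test tables as one long-format TSV.

    Column order is fixed: protein_id, count, contrast, log2FC, ordinary
    t and p, moderated t, p, BH-adjusted p, pooled/prior/posterior
    variance, residual df, prior df.
    """
    frames = []
    for (g1, g2), tbl in fit.results.items():
        out = tbl.reset_index()
        out.insert(1, "count", fit.count if fit.count is not None else np.nan)
        out.insert(2, "contrast", f"{g1}:{g2}")
        for col in ("t_ord", "p_ord"):
            if col not in out.columns:
                out[col] = np.nan
        out["pooled_var"] = fit.base.pooled_var
        out["prior_var"] = fit.s0_sq
        out["post_var"] = fit.post_var
        out["resid_df"] = fit.base.resid_df
        out["prior_df"] = fit.d0
        frames.append(out[_RESULT_COLUMNS])
    if frames:
        result = pd.concat(frames, axis=0, ignore_index=True)
    else:
        result = pd.DataFrame(columns=_RESULT_COLUMNS)
    result.to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys are rejected."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
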