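"""Summarize PSM/peptide intensities to protein-level log2 relative abundance.

Two summarization schemes are provided:

median sweep
    (1) log2-transform the raw intensities; (2) centre every PSM row by
    its median across samples; (3) per protein and sample, take the
    median over the protein's rows; (4) centre every sample column by its
    median. After the sweep all column medians are zero — the procedure
    assumes the treatment leaves total protein content unchanged.

reference ratio
    For designs with internal reference channels: divide each row's
    intensities by the (mean of the) reference channel intensities, take
    per-protein per-sample medians of the ratios, log2-transform, and
    drop the reference columns.

For multi-batch (multi-TMT-set) data, summarization runs per batch, the
per-batch matrices are inner-joined on protein id (a protein must be
quantified in every batch), and the per-batch PSM counts are collapsed to
one integer per protein by a configurable metric; the minimum is the
recommended default, reflecting that the weakest batch limits the
quantification quality of the combined profile.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import DesignSpec, ProteinMatrix, QuantTable, ValidationError

__all__ = ["median_sweep", "reference_ratio", "combine_counts"]

logger = logging.getLogger(__name__)

_COUNT_METRICS = {
    "min": lambda df: df.min(axis=1),
    "max": lambda df: df.max(axis=1),
    "sum": lambda df: df.sum(axis=1),
    "mean": lambda df: df.mean(axis=1),
    "median": lambda df: df.median(axis=1),
}


def _split_batches(table: QuantTable) -> list[tuple[str | None, pd.DataFrame]]:
    if not table.has_batches:
        return [(None, table.data)]
    return [(b, sub) for b, sub in table.data.groupby("batch", sort=True)]


def _median_sweep_block(block: pd.DataFrame, sample_ids: list[str]) -> pd.DataFrame:
    """Steps 1-4 of the median sweep on one batch; returns proteins x samples
    plus a 'count' column. Rows with any missing intensity are dropped."""
    inten = block[sample_ids].astype(float)
    complete = inten.notna().all(axis=1) & (inten > 0).all(axis=1)
    n_drop = int((~complete).sum())
    if n_drop:
        logger.info("median_sweep: dropped %d incomplete rows", n_drop)
    inten = inten[complete]
    if inten.empty:
        raise ValidationError("median_sweep: all rows dropped as incomplete")
    log2i = np.log2(inten)
    ratios = log2i.sub(log2i.median(axis=1), axis=0)  # row-median sweep
    ratios["__protein__"] = block.loc[complete, "protein_id"].to_numpy()
    prot = ratios.groupby("__protein__", sort=False).median()
    counts = ratios.groupby("__protein__", sort=False).size()
    prot = prot.sub(prot.median(axis=0), axis=1)  # column-median sweep
    prot["count"] = counts
    prot.index.name = "protein_id"
    return prot


def median_sweep(table: QuantTable) -> ProteinMatrix:
    """Median-sweep summarization of a PSM/peptide table.

    Multi-batch tables are swept per batch and inner-joined; the returned
    matrix carries per-batch counts (``per_batch_count``) and a default
    combined count using the ``min`` metric.
    """
    blocks = _split_batches(table)
    mats, counts = [], {}
    for batch, block in blocks:
        prot = _median_sweep_block(block, table.sample_ids)
        counts[batch] = prot.pop("count")
        if batch is not None:
            prot.columns = [f"{batch}.{s}" for s in prot.columns]
        mats.append(prot)
    joined = pd.concat(mats, axis=1, join="inner")
    if joined.empty:
        raise ValidationError("median_sweep: no protein quantified in all batches")
    if len(blocks) == 1:
        count = counts[blocks[0][0]].loc[joined.index]
        return ProteinMatrix(values=joined, count=count)
    per_batch = pd.DataFrame(
        {b: c for b, c in counts.items()}
    ).loc[joined.index]
    combined = combine_counts(per_batch, "min")
    return ProteinMatrix(values=joined, count=combined, per_batch_count=per_batch)


def reference_ratio(table: QuantTable, design: DesignSpec) -> ProteinMatrix:
    """Reference-channel ratio summarization.

    Every batch must declare at least one reference sample in the design;
    with several references the denominator is their mean intensity.
    """
    refs_by_batch = design.references_by_batch()
    if not design.reference_samples:
        raise ValidationError("reference_ratio requires reference samples in design")
    blocks = _split_batches(table)
    mats, counts = [], {}
    for batch, block in blocks:
        key = batch if batch is not None else ""
        refs = refs_by_batch.get(key) or refs_by_batch.get("", [])
        refs = [r for r in refs if r in table.sample_ids]
        if not refs:
            raise ValidationError(f"batch {batch!r} has no reference sample")
        targets = [
            s for s in table.sample_ids if s not in design.reference_samples
        ]
        inten = block[table.sample_ids].astype(float)
        denom = inten[refs].mean(axis=1)
        usable = denom.notna() & (denom > 0) & inten[targets].notna().all(axis=1)
        usable &= (inten[targets] > 0).all(axis=1)
        n_drop = int((~usable).sum())
        if n_drop:
            logger.info("reference_ratio: dropped %d rows", n_drop)
        if not usable.any():
            raise ValidationError("reference_ratio: all rows dropped")
        ratios = inten.loc[usable, targets].div(denom[usable], axis=0)
        ratios["__protein__"] = block.loc[usable, "protein_id"].to_numpy()
        prot = np.log2(ratios.groupby("__protein__", sort=False).median())
        counts[batch] = ratios.groupby("__protein__", sort=False).size()
        if batch is not None:
            prot.columns = [f"{batch}.{s}" for s in prot.columns]
        prot.index.name = "protein_id"
        mats.append(prot)
    joined = pd.concat(mats, axis=1, join="inner")
    if joined.empty:
        raise ValidationError("reference_ratio: no protein quantified in all batches")
    if len(blocks) == 1:
        count = counts[blocks[0][0]].loc[joined.index]
        return ProteinMatrix(values=joined, count=count)
    per_batch = pd.DataFrame({b: c for b, c in counts.items()}).loc[joined.index]
    combined = combine_counts(per_batch, "min")
    return ProteinMatrix(values=joined, count=combined, per_batch_count=per_batch)


def combine_counts(per_batch: pd.DataFrame, metric: str = "min") -> pd.Series:
    """Collapse per-batch counts (proteins x batches) to one integer each.

    ``mean``/``median`` are rounded half-up and floored at 1 so the result
    remains a valid count.
    """
    if metric not in _COUNT_METRICS:
        raise ValidationError(f"unknown count metric {metric!r}")
    if per_batch.isna().any().any():
        raise ValidationError("combine_counts requires counts in every batch")
    combined = _COUNT_METRICS[metric](per_batch.astype(float))
    combined = np.floor(combined + 0.5)  # round half-up
    return combined.clip(lower=1).astype(int)
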