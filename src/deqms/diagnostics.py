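"""Diagnostics: variance-vs-count profiles, trend RSS, and partial AUC.

These reproduce the standard quality views for a count-dependent variance
model: a binned summary of within-group standard deviation by PSM count,
the residual sum of squares of a fitted variance trend (overall and per
count bin, for comparing count metrics or trend vs flat prior), and the
partial area under the ROC curve restricted to a high-specificity range
for benchmarking score vectors against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .datamodel import DesignSpec, ProteinMatrix, ValidationError
from .ebayes import VarianceTrend
from .linear_models import fit_group_means

__all__ = [
    "VarianceProfile",
    "variance_profile",
    "rss_of_fit",
    "count_metric_rss",
    "pauc",
]


@dataclass
class VarianceProfile:
    """Per-count-bin summary of within-group standard deviation."""

    count_bins: list[int]           # last bin pools counts >= max_count
    summary: pd.DataFrame           # index bin; n_proteins, q25, median, q75
    max_count: int


def _bin_counts(counts: np.ndarray, max_count: int) -> np.ndarray:
    return np.minimum(counts, max_count)


def variance_profile(
    matrix: ProteinMatrix, design: DesignSpec, max_count: int = 20
) -> VarianceProfile:
    """Quartiles of pooled within-group standard deviation by PSM count.

    Counts above ``max_count`` are merged into the last bin.
    """
    base = fit_group_means(matrix, design)
    sd = np.sqrt(base.pooled_var)
    bins = _bin_counts(matrix.count.to_numpy(), max_count)
    df = pd.DataFrame({"bin": bins, "sd": sd})
    grouped = df.groupby("bin")["sd"]
    summary = pd.DataFrame(
        {
            "n_proteins": grouped.size(),
            "q25": grouped.quantile(0.25),
            "median": grouped.median(),
            "q75": grouped.quantile(0.75),
        }
    )
    return VarianceProfile(
        count_bins=summary.index.tolist(), summary=summary, max_count=max_count
    )


def rss_of_fit(
    trend: VarianceTrend, counts: np.ndarray | None = None, max_count: int = 20
) -> tuple[float, pd.Series | None]:
    """Residual sum of squares of the variance trend, total and per bin.

    RSS = sum (logVAR - fitted_logVAR)^2 over proteins with a defined log
    variance. For a flat (constant-covariate) fit this measures how badly
    a single prior represents count-heterogeneous variances.
    """
    ok = np.isfinite(trend.logVAR)
    resid2 = (trend.logVAR[ok] - trend.fitted_logVAR[ok]) ** 2
    total = float(resid2.sum())
    per_bin = None
    if counts is not None:
        bins = _bin_counts(np.asarray(counts)[ok], max_count)
        per_bin = pd.Series(resid2).groupby(bins).sum()
        per_bin.index.name = "count_bin"
    return total, per_bin


def count_metric_rss(
    matrix: ProteinMatrix,
    design: DesignSpec,
    metrics: tuple[str, ...] = ("min", "mean", "median", "sum", "max"),
    span: float = 0.75,
    degree: int = 2,
) -> pd.Series:
    """Trend RSS for each way of collapsing per-batch counts to one integer.

    For every metric the per-batch counts are combined, the log pooled
    variance is loess-regressed on log2 of the combined count, and the
    total RSS is reported; the metric with the smallest RSS predicts the
    actual variance best.
    """
    from .ebayes import fit_trend
    from .summarize import combine_counts

    if matrix.per_batch_count is None:
        raise ValidationError("count_metric_rss requires per-batch counts")
    base = fit_group_means(matrix, design)
    ok = base.pooled_var > 0
    logvar = np.log(base.pooled_var[ok])
    out = {}
    for metric in metrics:
        combined = combine_counts(matrix.per_batch_count, metric).to_numpy()
        x = np.log2(combined.astype(float))[ok]
        fitted, _ = fit_trend(x, logvar, span=span, degree=degree)
        out[metric] = float(((logvar - fitted) ** 2).sum())
    return pd.Series(out, name="rss_total")


def pauc(
    scores: np.ndarray, labels: np.ndarray, spec_floor: float = 0.95
) -> float:
    """Partial AUC over specificity in [spec_floor, 1], as a percentage.

    The ROC is swept over descending score thresholds (tied scores form a
    single step); the trapezoidal area for false-positive rate in
    [0, 1 - spec_floor] is normalized by its maximum (1 - spec_floor) and
    returned in percent, so a perfect separator scores 100.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not 0 < spec_floor < 1:
        raise ValidationError("spec_floor must be in (0, 1)")
    if labels.min() == labels.max():
        raise ValidationError("pauc requires both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    fpr_max = 1.0 - spec_floor
    # interpolate the ROC at the cutoff and integrate the clipped curve
    tpr_cut = np.interp(fpr_max, fpr, tpr)
    keep = fpr < fpr_max
    fpr_c = np.append(fpr[keep], fpr_max)
    tpr_c = np.append(tpr[keep], tpr_cut)
    area = np.trapezoid(tpr_c, fpr_c)
    return float(area / fpr_max * 100.0)
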