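"""Per-protein group-mean linear models: pooled variance, ordinary t, ANOVA F.

Every protein is modelled as a one-factor layout: sample j in group i has
mean mu_i and common residual variance. The pooled variance

    s_p^2 = sum_i (n_i - 1) s_i^2 / sum_i (n_i - 1)

uses all groups (not only the contrasted pair), on d_g = N - k residual
degrees of freedom, and is the quantity that empirical-Bayes moderation
shrinks. The ordinary two-sample t uses the unpooled (Welch) denominator
sqrt(s_1^2/n_1 + s_2^2/n_2) with Welch-Satterthwaite degrees of freedom;
the ANOVA F divides the between-group mean square by s_p^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import DesignSpec, ProteinMatrix, ValidationError

__all__ = ["LinearFit", "fit_group_means", "ordinary_t", "anova_f"]


@dataclass
class LinearFit:
    """Group means and pooled within-group variance per protein."""

    protein_ids: list[str]
    group_names: list[str]
    group_ns: np.ndarray          # (k,)
    group_means: np.ndarray       # (p, k)
    group_vars: np.ndarray        # (p, k); NaN where n_i < 2
    pooled_var: np.ndarray        # (p,)
    resid_df: int                 # d_g = N - k, shared by all proteins
    overall_mean: np.ndarray      # (p,)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def group_index(self, name: str) -> int:
        try:
            return self.group_names.index(name)
        except ValueError:
            raise ValidationError(f"unknown group {name!r}") from None


def fit_group_means(matrix: ProteinMatrix, design: DesignSpec) -> LinearFit:
    """Fit per-protein group means and pooled variance.

    Groups of size 1 are allowed (they contribute a mean but 0 residual
    df); the fit fails only if no group has replication at all.
    """
    design.validate_against(matrix.sample_ids)
    groups = {
        g: [s for s in members if s in matrix.sample_ids]
        for g, members in design.groups().items()
    }
    groups = {g: m for g, m in groups.items() if m}
    names = list(groups)
    k = len(names)
    vals = matrix.values.to_numpy(dtype=float)
    col_of = {s: i for i, s in enumerate(matrix.sample_ids)}

    ns = np.array([len(groups[g]) for g in names])
    n_total = int(ns.sum())
    resid_df = n_total - k
    if resid_df < 1:
        raise ValidationError("no residual degrees of freedom (all groups size 1)")

    p = vals.shape[0]
    means = np.empty((p, k))
    gvars = np.full((p, k), np.nan)
    for j, g in enumerate(names):
        cols = [col_of[s] for s in groups[g]]
        block = vals[:, cols]
        means[:, j] = block.mean(axis=1)
        if len(cols) > 1:
            gvars[:, j] = block.var(axis=1, ddof=1)

    w = (ns - 1).astype(float)
    pooled = np.nansum(np.where(w > 0, gvars, 0.0) * w, axis=1) / w.sum()
    overall = (means * ns).sum(axis=1) / n_total

    return LinearFit(
        protein_ids=matrix.protein_ids,
        group_names=names,
        group_ns=ns,
        group_means=means,
        group_vars=gvars,
        pooled_var=pooled,
        resid_df=resid_df,
        overall_mean=overall,
    )


def _t_pvalue(t: np.ndarray, df: np.ndarray | float) -> np.ndarray:
    """Two-sided p from a t distribution; infinite df means standard normal."""
    df = np.asarray(df, dtype=float)
    p = np.where(
        np.isinf(df),
        2.0 * stats.norm.sf(np.abs(t)),
        2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1e-300)),
    )
    return p


def ordinary_t(
    fit: LinearFit, contrast: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Welch two-sample t (first group minus second) and two-sided p.

    The denominator is the unpooled sqrt(s1^2/n1 + s2^2/n2); p-values use
    Welch-Satterthwaite degrees of freedom. Zero-variance degenerate
    proteins give t = 0 (p = 1) when the means also agree, +-inf (p = 0)
    otherwise.
    """
    i1, i2 = fit.group_index(contrast[0]), fit.group_index(contrast[1])
    n1, n2 = fit.group_ns[i1], fit.group_ns[i2]
    if n1 < 2 or n2 < 2:
        raise ValidationError("ordinary t requires >= 2 replicates per group")
    diff = fit.group_means[:, i1] - fit.group_means[:, i2]
    v1, v2 = fit.group_vars[:, i1], fit.group_vars[:, i2]
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    zero_se = se2 == 0
    with np.errstate(invalid="ignore"):
        t = np.where(zero_se, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    df = np.where(zero_se, float(n1 + n2 - 2), df)
    p = _t_pvalue(t, df)
    p = np.where(zero_se & (diff == 0), 1.0, p)
    return t, p


def anova_f(fit: LinearFit) -> tuple[np.ndarray, np.ndarray]:
    """One-way ANOVA F per protein and its p-value.

    F = between-group mean square / pooled variance, on (k - 1, d_g)
    degrees of freedom. For two groups this is exactly the square of the
    pooled two-sample t.
    """
    k = len(fit.group_names)
    if k < 2:
        raise ValidationError("ANOVA requires >= 2 groups")
    between = (
        fit.group_ns * (fit.group_means - fit.overall_mean[:, None]) ** 2
    ).sum(axis=1) / (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = between / fit.pooled_var
    F = np.where(fit.pooled_var == 0, np.where(between == 0, 0.0, np.inf), F)
    p = stats.f.sf(F, k - 1, fit.resid_df)
    return F, p
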