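"""Empirical-Bayes variance moderation with a count-dependent prior.

The log of a sample variance on d_g degrees of freedom is distributed as a
constant plus a Fisher's-Z variable, which gives closed-form moments in
terms of the digamma (psi) and trigamma (psi') functions. Writing

    e_g = log(s_p^2) - psi(d_g/2) + log(d_g/2)

the prior variance s0^2 and prior degrees of freedom d0 of a scaled
inverse-chi-square variance prior satisfy

    E(e_g)   = log(s0^2) - psi(d0/2) + log(d0/2)
    Var(e_g) = psi'(d_g/2) + psi'(d0/2)

Instead of a single prior expectation, E(e_g) is replaced per protein by
the value predicted from a loess regression of log variance on the log2
PSM/peptide count (or on mean log2 abundance for the intensity-trend
variant), making the prior variance depend on quantification depth. d0 is
then found from the moment equation

    psi'(d0/2) = mean[(e_g - pred(e_g))^2] - psi'(d_g/2)

by a 0.1-step grid search that stops when |lhs - rhs| first increases.
The posterior variance is the df-weighted average
(d_g s_p^2 + d0 s0^2)/(d_g + d0), and the moderated t refers the contrast
to a t distribution on d_g + d0 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datamodel import DesignSpec, ProteinMatrix, RunConfig, ValidationError
from .linear_models import LinearFit, _t_pvalue, fit_group_means, ordinary_t
from .loess import LoessSmoother

__all__ = [
    "VarianceTrend",
    "EBayesFit",
    "compute_eg",
    "fit_trend",
    "estimate_d0",
    "trigamma_inverse",
    "prior_variance",
    "posterior_variance",
    "moderated_t",
    "moderated_f",
    "bh_adjust",
    "spectra_count_ebayes",
]


@dataclass
class VarianceTrend:
    """Loess trend of log pooled variance against the covariate."""

    x: np.ndarray                 # covariate (log2 count / mean abundance / 0)
    logVAR: np.ndarray            # natural log of pooled variance
    fitted_logVAR: np.ndarray
    e_g: np.ndarray
    pred_e_g: np.ndarray
    loess_span: float
    loess_degree: int
    smoother: LoessSmoother | None = None


@dataclass
class EBayesFit:
    """Complete moderated fit: hyperparameters, variances and test tables."""

    base: LinearFit
    trend: VarianceTrend
    d0: float
    s0_sq: np.ndarray
    post_var: np.ndarray
    total_df: float
    results: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    f_table: pd.DataFrame | None = None
    covariate_mode: str = "count"
    count: np.ndarray | None = None


def compute_eg(pooled_var: np.ndarray, d_g: float) -> np.ndarray:
    """Centred log sample variance e_g (natural logs).

    Only strictly positive variances are meaningful here; callers exclude
    zeros beforehand.
    """
    if d_g < 1:
        raise ValidationError("residual df must be >= 1")
    pooled_var = np.asarray(pooled_var, dtype=float)
    if np.any(pooled_var <= 0):
        raise ValidationError("compute_eg requires strictly positive variances")
    return np.log(pooled_var) - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)


def fit_trend(
    x: np.ndarray,
    logVAR: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
) -> tuple[np.ndarray, LoessSmoother | None]:
    """Loess fit of log variance on the covariate.

    A constant covariate (or one with too few distinct values for the
    polynomial degree) degenerates to the flat fit mean(logVAR), i.e. the
    classic single-prior moderation.
    """
    x = np.asarray(x, dtype=float)
    logVAR = np.asarray(logVAR, dtype=float)
    if np.unique(x).size == 1:
        return np.full_like(logVAR, logVAR.mean()), None
    sm = LoessSmoother(span=span, degree=degree).fit(x, logVAR)
    return sm.fitted_, sm


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve psi'(x) = y for x > 0 by Newton iteration.

    Uses the monotone transform 1/psi'(x) (approximately linear in x), so
    the iteration converges monotonically from the starting value
    x = 0.5 + 1/y.
    """
    if not y > 0:
        raise ValidationError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < tol:
            break
    return float(x)


def estimate_d0(
    e_g: np.ndarray,
    pred_e_g: np.ndarray,
    d_g: float,
    grid_step: float = 0.1,
    grid_max: float = 500.0,
) -> float:
    """Prior degrees of freedom from the moment equation, on a grid.

    Scans d0 = grid_step, 2*grid_step, ... and returns the value at which
    |mean[(e_g - pred)^2] - psi'(d_g/2) - psi'(d0/2)| first stops
    decreasing. Returns +inf when the excess spread of e_g around the
    trend is <= psi'(d_g/2) (no finite d0 solves the equation) or when the
    cap is reached while still improving.
    """
    e_g = np.asarray(e_g, dtype=float)
    pred_e_g = np.asarray(pred_e_g, dtype=float)
    if e_g.size == 0:
        raise ValidationError("estimate_d0 requires a non-empty e_g")
    excess = float(np.mean((e_g - pred_e_g) ** 2)) - special.polygamma(1, d_g / 2.0)
    if excess <= 0:
        return np.inf
    best = np.inf
    k = 0
    while (k + 1) * grid_step <= grid_max + 1e-12:
        k += 1
        d0 = k * grid_step
        diff = abs(excess - special.polygamma(1, d0 / 2.0))
        if diff > best:
            return (k - 1) * grid_step
        best = diff
    warnings.warn(
        "d0 grid search hit the cap while still improving; returning +inf",
        RuntimeWarning,
        stacklevel=2,
    )
    return np.inf


def estimate_d0_newton(e_g: np.ndarray, pred_e_g: np.ndarray, d_g: float) -> float:
    """Non-grid d0 estimate via the trigamma inverse (continuous solution)."""
    excess = float(np.mean((np.asarray(e_g) - np.asarray(pred_e_g)) ** 2))
    excess -= special.polygamma(1, d_g / 2.0)
    if excess <= 0:
        return np.inf
    return 2.0 * trigamma_inverse(excess)


def _prior_log_adjustment(d0: float) -> float:
    """psi(d0/2) - log(d0/2); tends to 0 as d0 -> inf."""
    if np.isinf(d0):
        return 0.0
    return float(special.digamma(d0 / 2.0) - np.log(d0 / 2.0))


def prior_variance(
    fitted_logVAR: np.ndarray, d0: float, d_g: float
) -> np.ndarray:
    """Per-protein prior variance s0^2 from the fitted trend.

    s0^2 = exp(pred(e_g) + psi(d0/2) - log(d0/2)) with
    pred(e_g) = fitted(logVAR) - psi(d_g/2) + log(d_g/2).
    """
    if not (d0 > 0):
        raise ValidationError("prior_variance requires d0 > 0")
    pred_eg = (
        np.asarray(fitted_logVAR, dtype=float)
        - special.digamma(d_g / 2.0)
        + np.log(d_g / 2.0)
    )
    return np.exp(pred_eg + _prior_log_adjustment(d0))


def posterior_variance(
    pooled_var: np.ndarray, s0_sq: np.ndarray, d_g: float, d0: float
) -> np.ndarray:
    """Df-weighted average of pooled and prior variance."""
    pooled_var = np.asarray(pooled_var, dtype=float)
    s0_sq = np.asarray(s0_sq, dtype=float)
    if np.isinf(d0):
        return s0_sq.copy()
    return (d_g * pooled_var + d0 * s0_sq) / (d_g + d0)


def moderated_t(
    base: LinearFit,
    post_var: np.ndarray,
    d0: float,
    contrast: tuple[str, str],
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t for a two-group contrast and its two-sided p.

    t = (mean_G1 - mean_G2) / (s_post * sqrt(1/n1 + 1/n2)), referred to a
    t distribution on d_g + d0 df (standard normal when d0 is infinite).
    """
    i1, i2 = base.group_index(contrast[0]), base.group_index(contrast[1])
    n1, n2 = base.group_ns[i1], base.group_ns[i2]
    diff = base.group_means[:, i1] - base.group_means[:, i2]
    scale2 = post_var * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(scale2)
        t = np.where(
            scale2 == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t
        )
    df = base.resid_df + d0
    p = _t_pvalue(t, df)
    p = np.where((scale2 == 0) & (diff == 0), 1.0, p)
    return t, p


def moderated_f(
    base: LinearFit, post_var: np.ndarray, d0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated one-way ANOVA F: between-group mean square over the
    posterior variance, on (k - 1, d_g + d0) df."""
    k = len(base.group_names)
    if k < 2:
        raise ValidationError("moderated F requires >= 2 groups")
    between = (
        base.group_ns * (base.group_means - base.overall_mean[:, None]) ** 2
    ).sum(axis=1) / (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = between / post_var
    F = np.where(post_var == 0, np.where(between == 0, 0.0, np.inf), F)
    if np.isinf(d0):
        p = stats.chi2.sf(F * (k - 1), k - 1)
    else:
        p = stats.f.sf(F, k - 1, base.resid_df + d0)
    return F, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _covariate(
    matrix: ProteinMatrix, base: LinearFit, mode: str
) -> np.ndarray:
    if mode == "count":
        return np.log2(matrix.count.to_numpy(dtype=float))
    if mode == "intensity":
        return matrix.values.to_numpy(dtype=float).mean(axis=1)
    if mode == "constant":
        return np.zeros(matrix.n_proteins)
    raise ValidationError(f"unknown covariate_mode {mode!r}")


def spectra_count_ebayes(
    matrix: ProteinMatrix,
    design: DesignSpec,
    config: RunConfig | None = None,
    contrasts: list[tuple[str, str]] | None = None,
) -> EBayesFit:
    """Full count-dependent empirical-Bayes pipeline on a protein matrix.

    Orchestrates the linear fit, the variance trend against the chosen
    covariate, d0 estimation, prior and posterior variances, moderated
    t (per contrast) and F, and BH adjustment. Proteins with zero pooled
    variance are excluded from trend and d0 estimation but kept in the
    output with posterior variance equal to their prior variance.
    """
    config = config or RunConfig()
    base = fit_group_means(matrix, design)
    x_all = _covariate(matrix, base, config.covariate_mode)

    ok = base.pooled_var > 0
    if ok.sum() < 2:
        raise ValidationError("too few proteins with positive pooled variance")
    logvar = np.log(base.pooled_var[ok])
    d_g = float(base.resid_df)

    fitted_ok, smoother = fit_trend(
        x_all[ok], logvar, span=config.loess_span, degree=config.loess_degree
    )
    if smoother is not None:
        fitted_all = smoother.predict(x_all)
    else:
        fitted_all = np.full(matrix.n_proteins, logvar.mean())
    fitted_all[ok] = fitted_ok

    e_g = compute_eg(base.pooled_var[ok], d_g)
    offset = -special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    pred_e_g_all = fitted_all + offset
    d0 = estimate_d0(
        e_g, pred_e_g_all[ok], d_g, config.d0_grid_step, config.d0_grid_max
    )
    s0_sq = prior_variance(fitted_all, d0, d_g)
    post_var = posterior_variance(base.pooled_var, s0_sq, d_g, d0)
    post_var[~ok] = s0_sq[~ok]

    trend = VarianceTrend(
        x=x_all,
        logVAR=np.where(ok, np.log(np.where(ok, base.pooled_var, 1.0)), np.nan),
        fitted_logVAR=fitted_all,
        e_g=np.where(ok, np.log(np.where(ok, base.pooled_var, 1.0)) + offset, np.nan),
        pred_e_g=pred_e_g_all,
        loess_span=config.loess_span,
        loess_degree=config.loess_degree,
        smoother=smoother,
    )

    fit = EBayesFit(
        base=base,
        trend=trend,
        d0=d0,
        s0_sq=s0_sq,
        post_var=post_var,
        total_df=d_g + d0,
        covariate_mode=config.covariate_mode,
        count=matrix.count.to_numpy(),
    )

    if contrasts is None:
        contrasts = design.contrasts
    sizes = design.group_sizes()
    for g1, g2 in contrasts:
        i1, i2 = base.group_index(g1), base.group_index(g2)
        logfc = base.group_means[:, i1] - base.group_means[:, i2]
        tmod, pmod = moderated_t(base, post_var, d0, (g1, g2))
        tbl = pd.DataFrame(
            {
                "protein_id": base.protein_ids,
                "log2FC": logfc,
                "t_mod": tmod,
                "p_mod": pmod,
                "q_mod": bh_adjust(pmod),
            }
        ).set_index("protein_id")
        if sizes.get(g1, 0) >= 2 and sizes.get(g2, 0) >= 2:
            tord, pord = ordinary_t(base, (g1, g2))
            tbl.insert(1, "t_ord", tord)
            tbl.insert(2, "p_ord", pord)
        fit.results[(g1, g2)] = tbl

    if len(base.group_names) >= 2:
        F, pF = moderated_f(base, post_var, d0)
        fit.f_table = pd.DataFrame(
            {
                "protein_id": base.protein_ids,
                "F_mod": F,
                "p_mod": pF,
                "q_mod": bh_adjust(pF),
            }
        ).set_index("protein_id")

    return fit
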