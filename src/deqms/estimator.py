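"""scikit-learn-style estimator wrapping the moderated-variance pipeline.

``SpectraCountEBayes`` follows the univariate-feature-testing shape
(compare ``sklearn.feature_selection``): ``X`` is samples x proteins,
``y`` holds the group label of each sample, and the per-protein PSM or
peptide counts enter as a fit parameter. After ``fit`` the estimator
exposes the hyperparameters (``d0_``), the per-protein variances and the
test machinery (``test`` for a two-group contrast, ``f_test`` across all
groups), and composes with sklearn model-selection utilities through
``get_params``/``set_params``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted, column_or_1d

from . import ebayes
from .datamodel import DesignSpec, ProteinMatrix, RunConfig, ValidationError
from .linear_models import fit_group_means

__all__ = ["SpectraCountEBayes"]


class SpectraCountEBayes(BaseEstimator):
    """Count-dependent empirical-Bayes moderated test.

    Parameters
    ----------
    covariate : {"count", "intensity", "constant"}
        What the log pooled variance is regressed on: log2 PSM/peptide
        count (the count-dependent prior), mean log2 abundance (the
        intensity-trend variant), or nothing (flat prior).
    span, degree : loess window fraction and polynomial degree.
    d0_grid_step, d0_grid_max : grid for the prior-df search.

    Attributes
    ----------
    groups_ : list of group labels (fit order).
    group_means_ : ndarray (n_proteins, n_groups).
    pooled_var_, prior_var_, posterior_var_ : ndarray (n_proteins,).
    resid_df_ : int; d0_ : float (may be +inf); total_df_ : float.
    trend_ : VarianceTrend with the fitted loess curve.
    """

    def __init__(
        self,
        covariate: str = "count",
        span: float = 0.75,
        degree: int = 2,
        d0_grid_step: float = 0.1,
        d0_grid_max: float = 500.0,
    ) -> None:
        self.covariate = covariate
        self.span = span
        self.degree = degree
        self.d0_grid_step = d0_grid_step
        self.d0_grid_max = d0_grid_max

    def _config(self) -> RunConfig:
        return RunConfig(
            loess_span=self.span,
            loess_degree=self.degree,
            d0_grid_step=self.d0_grid_step,
            d0_grid_max=self.d0_grid_max,
            covariate_mode=self.covariate,
        )

    def fit(self, X, y, counts=None):
        """Fit the moderated variance model.

        Parameters
        ----------
        X : array-like (n_samples, n_proteins)
            Log2 relative abundances.
        y : array-like (n_samples,)
            Group label per sample.
        counts : array-like (n_proteins,), required when covariate="count"
            PSM (labelled) or peptide (label-free) count per protein.
        """
        feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = check_array(X, dtype=float)
        y = column_or_1d(y)
        if len(y) != X.shape[0]:
            raise ValidationError("y must have one label per sample (row of X)")
        if counts is None:
            if self.covariate == "count":
                raise ValidationError('covariate="count" requires counts')
            counts = np.ones(X.shape[1], dtype=int)
        counts = np.asarray(counts)
        if counts.shape != (X.shape[1],):
            raise ValidationError("counts must have one entry per protein")

        protein_ids = feature_names or [f"p{i}" for i in range(X.shape[1])]
        sample_ids = [f"s{i}" for i in range(X.shape[0])]
        matrix = ProteinMatrix(
            values=pd.DataFrame(X.T, index=protein_ids, columns=sample_ids),
            count=pd.Series(counts, index=protein_ids),
        )
        design = DesignSpec(
            sample_to_group={s: str(g) for s, g in zip(sample_ids, y)}
        )
        fit = ebayes.spectra_count_ebayes(matrix, design, self._config(), contrasts=[])

        self.fit_ = fit
        self.matrix_ = matrix
        self.design_ = design
        self.n_features_in_ = X.shape[1]
        self.feature_names_ = protein_ids
        self.groups_ = fit.base.group_names
        self.group_ns_ = fit.base.group_ns
        self.group_means_ = fit.base.group_means
        self.pooled_var_ = fit.base.pooled_var
        self.resid_df_ = fit.base.resid_df
        self.trend_ = fit.trend
        self.d0_ = fit.d0
        self.total_df_ = fit.total_df
        self.prior_var_ = fit.s0_sq
        self.posterior_var_ = fit.post_var
        return self

    def test(self, group1: str, group2: str) -> pd.DataFrame:
        """Moderated (and, when possible, ordinary) t-test of group1 - group2.

        Returns a DataFrame indexed by protein with columns log2FC,
        t_mod, p_mod, q_mod and, for groups with >= 2 replicates each,
        t_ord / p_ord.
        """
        check_is_fitted(self, "fit_")
        base = fit_group_means(self.matrix_, self.design_)
        i1, i2 = base.group_index(str(group1)), base.group_index(str(group2))
        logfc = base.group_means[:, i1] - base.group_means[:, i2]
        tmod, pmod = ebayes.moderated_t(
            base, self.posterior_var_, self.d0_, (str(group1), str(group2))
        )
        tbl = pd.DataFrame(
            {
                "log2FC": logfc,
                "t_mod": tmod,
                "p_mod": pmod,
                "q_mod": ebayes.bh_adjust(pmod),
            },
            index=pd.Index(self.feature_names_, name="protein_id"),
        )
        if base.group_ns[i1] >= 2 and base.group_ns[i2] >= 2:
            from .linear_models import ordinary_t

            tord, pord = ordinary_t(base, (str(group1), str(group2)))
            tbl.insert(1, "t_ord", tord)
            tbl.insert(2, "p_ord", pord)
        return tbl

    def f_test(self) -> pd.DataFrame:
        """Moderated one-way ANOVA F across all fitted groups."""
        check_is_fitted(self, "fit_")
        base = fit_group_means(self.matrix_, self.design_)
        F, p = ebayes.moderated_f(base, self.posterior_var_, self.d0_)
        return pd.DataFrame(
            {"F_mod": F, "p_mod": p, "q_mod": ebayes.bh_adjust(p)},
            index=pd.Index(self.feature_names_, name="protein_id"),
        )
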