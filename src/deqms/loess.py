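"""Local polynomial regression (loess) with tricube weights.

Used to fit the natural-log pooled variance against the log2 PSM/peptide
count (or mean log2 abundance). Plain Gaussian loess: for each target
point, the ``ceil(span * n)`` nearest neighbours get tricube weights
``(1 - (d/h)^3)^3`` and a weighted polynomial of the configured degree is
solved; the prediction is the polynomial value at the target. No
robustness iterations. Predictions outside the fitted covariate range are
clamped to the boundary (the trend is not extrapolated).

Replicated x values are handled natively: they simply share weights.
When the data carry fewer distinct x values than ``degree + 1`` the model
degenerates to the weighted mean (flat trend) with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["LoessSmoother", "loess_fit"]


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


class LoessSmoother:
    """Degree-1/2 loess smoother.

    Parameters
    ----------
    span : float
        Fraction of points in each local window, in (0, 1].
    degree : int
        Local polynomial degree, 1 or 2.
    """

    def __init__(self, span: float = 0.75, degree: int = 2) -> None:
        if not 0 < span <= 1:
            raise ValueError("span must be in (0, 1]")
        if degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        self.span = span
        self.degree = degree

    def fit(self, x: np.ndarray, y: np.ndarray) -> "LoessSmoother":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
            raise ValueError("x and y must be finite")
        self.x_ = x
        self.y_ = y
        self.flat_ = np.unique(x).size < self.degree + 1
        if self.flat_:
            warnings.warn(
                "fewer distinct covariate values than degree + 1; "
                "falling back to a flat fit",
                RuntimeWarning,
                stacklevel=2,
            )
        self.fitted_ = self.predict(x)
        return self

    def predict(self, x0: np.ndarray) -> np.ndarray:
        x0 = np.atleast_1d(np.asarray(x0, dtype=float))
        if self.flat_:
            return np.full(x0.shape, float(np.mean(self.y_)))
        lo, hi = self.x_.min(), self.x_.max()
        x0c = np.clip(x0, lo, hi)  # clamp: no extrapolation of the trend
        out = np.empty_like(x0c)
        # fit once per unique target; counts as covariate give few targets
        uniq, inv = np.unique(x0c, return_inverse=True)
        preds = np.array([self._fit_at(t) for t in uniq])
        out[:] = preds[inv]
        return out

    def _fit_at(self, t: float) -> float:
        x, y = self.x_, self.y_
        n = x.size
        # neighbourhood size floor(span*n), as in the reference implementation
        q = min(n, max(int(np.floor(self.span * n + 1e-9)), self.degree + 1))
        d = np.abs(x - t)
        h = np.partition(d, q - 1)[q - 1]
        if h <= 0:
            # window collapsed onto replicated x: local mean of the ties
            return float(np.mean(y[d == 0]))
        w = _tricube(d / h)
        use = w > 0
        xs, ys, ws = x[use] - t, y[use], w[use]
        deg = min(self.degree, np.unique(xs).size - 1)
        if deg < 1:
            return float(np.average(ys, weights=ws))
        design = np.vander(xs, deg + 1, increasing=True)
        sw = np.sqrt(ws)
        beta, *_ = np.linalg.lstsq(design * sw[:, None], ys * sw, rcond=None)
        return float(beta[0])


def loess_fit(
    x: np.ndarray, y: np.ndarray, span: float = 0.75, degree: int = 2
) -> np.ndarray:
    """Fitted loess values of ``y`` on ``x`` at the training points."""
    return LoessSmoother(span=span, degree=degree).fit(x, y).fitted_
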