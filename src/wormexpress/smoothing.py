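"""Local polynomial (loess) smoothing.

Degree-2 loess with tricube weights over a span fraction of nearest
neighbours, evaluated at the observed abscissae.  Written in-house
because the installed statsmodels lowess is locally linear only;
degree 2 is the conventional default for mean-variance trend fitting.
"""

from __future__ import annotations

import numpy as np

__all__ = ["loess_fit"]


def loess_fit(x: np.ndarray, y: np.ndarray, span: float = 0.75,
              degree: int = 2) -> np.ndarray:
    """Fitted loess values at each x.

    Parameters
    ----------
    x, y : 1-D arrays of equal length
    span : fraction of points in each local window (0 < span <= 1)
    degree : local polynomial degree (1 or 2)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n != y.shape[0]:
        raise ValueError("x and y must have the same length")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    k = max(int(np.ceil(span * n)), degree + 1)
    k = min(k, n)

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    fitted_sorted = np.empty(n)

    for i in range(n):
        # window of k nearest neighbours in x (contiguous in sorted order)
        lo = np.searchsorted(xs, xs[i], side="left")
        left, right = lo, lo  # expand greedily toward nearest points
        left = max(0, i - k + 1)
        right = min(n, i + k)
        # choose the k nearest among candidates
        cand = np.arange(left, right)
        d = np.abs(xs[cand] - xs[i])
        sel = cand[np.argsort(d, kind="stable")[:k]]
        xw, yw = xs[sel], ys[sel]
        h = np.max(np.abs(xw - xs[i]))
        if h <= 0:
            fitted_sorted[i] = yw.mean()
            continue
        u = np.abs(xw - xs[i]) / h
        w = np.clip(1.0 - u ** 3, 0.0, None) ** 3
        w[u >= 1.0] = np.finfo(float).eps  # keep boundary points barely in
        t = xw - xs[i]
        cols = [np.ones_like(t), t] + ([t ** 2] if degree == 2 else [])
        A = np.column_stack(cols)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], yw * sw, rcond=None)
        fitted_sorted[i] = coef[0]

    fitted = np.empty(n)
    fitted[order] = fitted_sorted
    return fitted
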