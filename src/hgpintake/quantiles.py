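"""Weighted quantiles: the single percentile convention used package-wide.

Every percentile reported anywhere in the pipeline (assay summaries, usual-
and short-term intake distributions, subgroup medians) is computed by
:func:`weighted_quantile`: a weighted empirical quantile with linear
interpolation between adjacent order statistics on the cumulative-weight
scale.  Plotting positions are Hazen-type, ``p_k = (cw_k - w_k/2) / W`` for
the k-th order statistic with cumulative weight ``cw_k`` and total ``W``,
so that with equal weights and values ``1..100`` the median is ``50.5``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["weighted_quantile", "weighted_median"]


def weighted_quantile(values, q, weights=None):
    """Weighted empirical quantile(s) with linear interpolation.

    Parameters
    ----------
    values : array_like
        Sample values.
    q : float or array_like
        Quantile level(s) in [0, 1].
    weights : array_like, optional
        Positive sampling weights; equal weights if omitted.

    Returns
    -------
    float or ndarray
        Interpolated quantile(s); scalar if ``q`` is scalar.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size == 0:
        raise ValueError("weighted_quantile of empty sample")
    qa = np.asarray(q, dtype=float)
    if np.any((qa < 0) | (qa > 1)):
        raise ValueError("quantile levels must lie in [0, 1]")
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != x.shape:
            raise ValueError("weights must match values in length")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative with positive total")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ws = w[order]
    cw = np.cumsum(ws)
    total = cw[-1]
    # Hazen plotting positions on the cumulative-weight scale.
    p = (cw - 0.5 * ws) / total
    out = np.interp(qa, p, xs, left=xs[0], right=xs[-1])
    return float(out) if np.isscalar(q) or qa.ndim == 0 else out


def weighted_median(values, weights=None):
    """Weighted median under the package percentile convention."""
    return weighted_quantile(values, 0.5, weights)
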