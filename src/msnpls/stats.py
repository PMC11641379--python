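"""Shared statistical helpers."""

from __future__ import annotations

import numpy as np


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Parameters
    ----------
    p : array-like of float in [0, 1]
        Raw p-values.

    Returns
    -------
    q : ndarray
        Adjusted values, clipped to <= 1, in the input order.  The adjustment
        is order-preserving: q is a monotone function of p.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    # step-up: running minimum from the largest p downwards
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
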