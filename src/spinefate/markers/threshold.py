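"""Kapur-Sahoo-Wong (maximum entropy) threshold selection.

The threshold t splits the grey-level histogram into background (levels
<= t) and foreground (levels > t); the chosen t maximizes the sum of the
Shannon entropies of the two normalized class distributions. Ties are
broken toward the lowest optimal level.
"""

from __future__ import annotations

import numpy as np

__all__ = ["kapur_threshold", "kapur_criterion"]


def _histogram(image: np.ndarray) -> np.ndarray:
    if not np.issubdtype(image.dtype, np.integer):
        raise TypeError("kapur_threshold expects an integer-typed image or a histogram")
    if image.min() < 0:
        raise ValueError("negative grey levels unsupported")
    nbins = int(image.max()) + 1
    return np.bincount(image.ravel(), minlength=nbins).astype(float)


def kapur_criterion(hist: np.ndarray) -> np.ndarray:
    """Total entropy psi(t) for every candidate threshold t (NaN if invalid)."""
    hist = np.asarray(hist, dtype=float)
    p = hist / hist.sum()
    # s[t] = -sum_{i<=t} p_i ln p_i, with 0 ln 0 = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    s = -np.cumsum(plogp)
    w0 = np.cumsum(p)
    w1 = 1.0 - w0
    psi = np.full(hist.size, np.nan)
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h0 = s / w0 + np.log(w0)
        h1 = (s[-1] - s) / w1 + np.log(w1)
    psi[valid] = h0[valid] + h1[valid]
    return psi


def kapur_threshold(image_or_hist: np.ndarray) -> int:
    """Maximum-entropy threshold of an integer image or a grey-level histogram.

    Returns the lowest level t maximizing the summed background/foreground
    entropies; pixels strictly above t are foreground. Raises on a
    single-valued input (no valid split exists).
    """
    arr = np.asarray(image_or_hist)
    hist = _histogram(arr) if arr.ndim != 1 else arr.astype(float)
    if np.count_nonzero(hist) < 2:
        raise ValueError("histogram has fewer than two occupied bins: no valid split")
    psi = kapur_criterion(hist)
    best = np.nanmax(psi)
    # lowest level within numerical tolerance of the maximum
    candidates = np.flatnonzero(psi >= best - 1e-12)
    return int(candidates[0])
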