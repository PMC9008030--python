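"""Per-ROI brightness features for the marker-positivity model.

For each ROI and imaging channel, with channel threshold t:

* ``integral``   - sum of (I - t) over pixels with I > t (excess mass above
  threshold; exactly zero for a ROI sitting at the threshold),
* ``pct_above``  - percentage of ROI pixels above t,
* ``min_above``  - minimum brightness among above-threshold pixels
  (0 if none; ``has_above`` records whether any pixel exceeded t),
* ``mean``       - mean brightness over all ROI pixels.

Thresholds are computed per channel with the maximum-entropy method unless
supplied: a threshold derived from the GFP channel has no meaning on
another channel's intensity scale. The raw-sum variant of the integral
(sum of I over above-threshold pixels) is available via ``integral_mode``.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .segmentation import Roi
from .threshold import kapur_threshold

__all__ = ["extract_features", "model_feature_table", "BASE_FEATURES"]

BASE_FEATURES = ["integral", "pct_above", "min_above", "mean"]


def extract_features(
    channels: Mapping[str, np.ndarray],
    rois: Sequence[Roi],
    thresholds: Optional[Mapping[str, float]] = None,
    integral_mode: str = "excess",
) -> pd.DataFrame:
    """Tidy feature table: one row per (ROI, channel)."""
    if integral_mode not in ("excess", "raw"):
        raise ValueError("integral_mode must be 'excess' or 'raw'")
    thr = dict(thresholds) if thresholds else {}
    for name, img in channels.items():
        if name not in thr:
            thr[name] = kapur_threshold(np.asarray(img))
    rows = []
    for roi in rois:
        for name, img in channels.items():
            img = np.asarray(img)
            if roi.mask.shape != img.shape:
                raise ValueError("ROI mask does not match image shape")
            vals = img[roi.mask].astype(float)
            t = float(thr[name])
            above = vals[vals > t]
            if integral_mode == "excess":
                integral = float(np.sum(above - t))
            else:
                integral = float(np.sum(above))
            rows.append(
                {
                    "roi_id": roi.id,
                    "slice_id": roi.slice_id,
                    "channel": name,
                    "threshold": t,
                    "integral": integral,
                    "pct_above": 100.0 * above.size / vals.size,
                    "min_above": float(above.min()) if above.size else 0.0,
                    "has_above": bool(above.size),
                    "mean": float(vals.mean()),
                    "area_um2": roi.area_um2,
                }
            )
    return pd.DataFrame(rows)


def model_feature_table(
    features: pd.DataFrame,
    marker_channel: str,
    gfp_channel: str = "GFP",
    interactions: bool = True,
) -> pd.DataFrame:
    """Wide per-ROI design table for one marker channel.

    Columns: the four base features of the marker channel, their within-
    channel 2- and 3-way interactions (if requested), and the GFP offsets
    ``z_mean``, ``z_pct``, ``z_integral`` (entered into the model as fixed
    ln(Z) terms).
    """
    mk = features[features["channel"] == marker_channel].set_index(["slice_id", "roi_id"])
    gfp = features[features["channel"] == gfp_channel].set_index(["slice_id", "roi_id"])
    if mk.empty:
        raise ValueError(f"no rows for channel {marker_channel!r}")
    out = mk[BASE_FEATURES].copy()
    if interactions:
        for r in (2, 3):
            for combo in combinations(BASE_FEATURES, r):
                out[":".join(combo)] = np.prod([mk[c].to_numpy() for c in combo], axis=0)
    out["z_mean"] = gfp["mean"]
    out["z_pct"] = gfp["pct_above"]
    out["z_integral"] = gfp["integral"]
    return out.reset_index()
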