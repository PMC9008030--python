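"""Literature-derived priors for the marker-positivity coefficients.

Each molecular marker d gets a Normal(logit(p_d), 1) prior on its
coefficient, where p_d is the literature co-expression rate of that marker
with VIP cells, clipped to [0.05, 0.95] to avoid infinities on the logit
scale. The SST rate is the geometric mean of reported values {0.5, 0.05,
0.05} (zeros replaced by 0.05), approximately 0.108.

``PUBLISHED_PRIOR_MEANS`` holds the published rounded prior means verbatim
(e.g. CCK -1.61, which is logit(1/6) rather than logit(0.17) = -1.586);
``build_priors`` computes exact logits from probabilities.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy.special import logit
from scipy.stats import gmean

__all__ = [
    "DEFAULT_OVERLAP_PROBABILITIES",
    "PUBLISHED_PRIOR_MEANS",
    "build_priors",
    "sst_overlap_prior",
]

DEFAULT_OVERLAP_PROBABILITIES: dict[str, float] = {
    "VIP": 0.95,
    "PV": 0.05,
    "NPY": 0.08,
    "CCK": 0.17,
    "CR": 0.5,
    "SST": 0.11,
}

#: Published prior means on the logit scale (rounded as printed).
PUBLISHED_PRIOR_MEANS: dict[str, float] = {
    "VIP": 3.0,
    "PV": -3.0,
    "NPY": -2.4,
    "CCK": -1.61,
    "CR": 0.0,
    "SST": -2.1,
}


def sst_overlap_prior(reported=(0.5, 0.0, 0.0), floor: float = 0.05) -> float:
    """Geometric mean of reported SST/VIP overlap rates, zeros floored."""
    vals = [max(v, floor) for v in reported]
    return float(gmean(vals))


def build_priors(
    overlap_probabilities: Mapping[str, float],
    clip: tuple[float, float] = (0.05, 0.95),
) -> dict[str, float]:
    """Prior means on the logit scale from per-marker overlap probabilities."""
    out = {}
    for marker, p in overlap_probabilities.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability for {marker} outside [0, 1]: {p}")
        out[marker] = float(logit(np.clip(p, *clip)))
    return out
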