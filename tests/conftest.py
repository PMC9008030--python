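import numpy as np
import pandas as pd
import pytest

from spinefate.dynamics import FateMatrix


def make_fate_matrix(patterns, days, lengths=None, mouse_map=None):
    """FateMatrix from {dendrite: {spine: presence tuple}} literals."""
    rows = []
    for dend, spines in patterns.items():
        mouse = (mouse_map or {}).get(dend, "m0")
        for spine, pattern in spines.items():
            for day, present in zip(days, pattern):
                rows.append((mouse, dend, spine, float(day), int(present)))
    obs = pd.DataFrame(
        rows, columns=["mouse_id", "dendrite_id", "spine_id", "session_day", "present"]
    )
    ser = pd.Series(lengths) if lengths else None
    return FateMatrix(observations=obs, dendrite_length_um=ser)


@pytest.fixture
def hand_fate_matrix():
    """10 day-0 spines on one dendrite, cumulative losses 0/2/5 at days 0/4/8."""
    days = [0, 4, 8]
    patterns = {
        "dA": {
            **{f"s{i}": (1, 1, 1) for i in range(5)},
            "s5": (1, 1, 0),
            "s6": (1, 1, 0),
            "s7": (1, 1, 0),
            "s8": (1, 0, 0),
            "s9": (1, 0, 0),
        }
    }
    return make_fate_matrix(patterns, days, lengths={"dA": 20.0})
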