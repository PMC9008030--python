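"""Spine densities, turnover ratios and survival fractions.

A :class:`FateMatrix` holds longitudinal presence/absence observations of
individual spines (one row per spine x imaging session) with dendrite and
mouse identifiers. From it the module computes

* linear spine density: spines present per micron of dendrite,
* the turnover ratio between two consecutive sessions t_i < t_j,
  R = (N_gained + N_lost) / (N_ti + N_tj),
* the survival fraction of a cohort, SF(t_i) = (N_0 - N_lost(0, t_i)) / N_0,
  for the day-0 cohort or for newly formed spines (time measured from each
  spine's first appearance),

together with spine-level event records (event = first session scored
absent, censored at the last session if still present) consumed by the
Kaplan-Meier and Cox models in :mod:`spinefate.survival`.

Loss is absorbing: once a spine is scored lost it stays lost for the
survival fraction, even if a protrusion later reappears at the same
position; such a protrusion should be annotated as a new spine id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "FateMatrix",
    "TurnoverResult",
    "SurvivalCurve",
    "spine_density",
    "turnover_ratio",
    "survival_fraction",
]

OBS_COLUMNS = ["mouse_id", "dendrite_id", "spine_id", "session_day", "present"]


@dataclass
class FateMatrix:
    """Tidy spine x session presence records plus per-dendrite lengths (um)."""

    observations: pd.DataFrame
    dendrite_length_um: pd.Series | None = None

    def __post_init__(self):
        missing = [c for c in OBS_COLUMNS if c not in self.observations.columns]
        if missing:
            raise ValueError(f"fate matrix missing columns: {missing}")
        obs = self.observations
        if (obs["session_day"] < 0).any():
            raise ValueError("session days must be non-negative")
        dup = obs.duplicated(["dendrite_id", "spine_id", "session_day"])
        if dup.any():
            raise ValueError("duplicate (dendrite, spine, session) observations")

    def presence(self, dendrite_id: str) -> pd.DataFrame:
        """Spine x session 0/1 pivot for one dendrite (absent-if-unrecorded)."""
        sub = self.observations[self.observations["dendrite_id"] == dendrite_id]
        piv = sub.pivot(index="spine_id", columns="session_day", values="present")
        return piv.fillna(0).astype(int).sort_index(axis=1)

    @property
    def dendrites(self) -> list[str]:
        return sorted(self.observations["dendrite_id"].unique())

    def mouse_of(self) -> pd.Series:
        m = self.observations.drop_duplicates("dendrite_id").set_index("dendrite_id")[
            "mouse_id"
        ]
        return m

    def to_csv(self, path) -> None:
        self.observations.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, lengths=None) -> "FateMatrix":
        obs = pd.read_csv(path)
        if lengths is not None:
            lengths = pd.Series(lengths) if not isinstance(lengths, pd.Series) else lengths
        return cls(observations=obs, dendrite_length_um=lengths)


def spine_density(fm: FateMatrix) -> pd.DataFrame:
    """Per-dendrite, per-session linear spine density (um^-1).

    Dendrites without a recorded length are dropped with a warning.
    """
    if fm.dendrite_length_um is None:
        raise ValueError("fate matrix carries no dendrite lengths")
    counts = (
        fm.observations.groupby(["mouse_id", "dendrite_id", "session_day"])["present"]
        .sum()
        .rename("n_spines")
        .reset_index()
    )
    lengths = fm.dendrite_length_um
    known = counts["dendrite_id"].isin(lengths.index)
    if not known.all():
        skipped = sorted(counts.loc[~known, "dendrite_id"].unique())
        warnings.warn(f"dendrites without length skipped: {skipped}")
        counts = counts[known]
    if (lengths.loc[counts["dendrite_id"].unique()] <= 0).any():
        raise ValueError("dendrite lengths must be positive")
    counts["length_um"] = counts["dendrite_id"].map(lengths)
    counts["density_per_um"] = counts["n_spines"] / counts["length_um"]
    return counts


@dataclass
class TurnoverResult:
    """Per-dendrite turnover ratios for consecutive session pairs."""

    per_pair: pd.DataFrame  # dendrite_id, mouse_id, t_i, t_j, gained, lost, n_ti, n_tj, tor
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self):
        g = self.per_pair.dropna(subset=["tor"]).groupby(["t_i", "t_j"])["tor"]
        self.summary = g.agg(["mean", "std", "count"]).reset_index()

    def with_spacing(self, days: float) -> pd.DataFrame:
        """Pairs whose spacing is exactly ``days`` (e.g. the 4-day TOR)."""
        pp = self.per_pair
        return pp[np.isclose(pp["t_j"] - pp["t_i"], days)]


def turnover_ratio(
    fm: FateMatrix, t_i: float | None = None, t_j: float | None = None
) -> TurnoverResult:
    """Turnover ratio R = (gained + lost) / (N_ti + N_tj) per dendrite.

    With ``t_i``/``t_j`` given, only that session pair is evaluated (it must
    be a consecutive pair for each dendrite that has both sessions);
    otherwise every consecutive pair of each dendrite's own observed
    sessions is computed. Pairs with N_ti + N_tj = 0 yield a missing ratio.
    """
    mouse_of = fm.mouse_of()
    rows = []
    for dend in fm.dendrites:
        piv = fm.presence(dend)
        days = np.asarray(piv.columns, dtype=float)
        if len(days) < 2:
            continue
        pairs = list(zip(days[:-1], days[1:]))
        if t_i is not None or t_j is not None:
            pairs = [p for p in pairs if np.isclose(p[0], t_i) and np.isclose(p[1], t_j)]
        for a, b in pairs:
            pa = piv[a].to_numpy().astype(bool)
            pb = piv[b].to_numpy().astype(bool)
            gained = int((~pa & pb).sum())
            lost = int((pa & ~pb).sum())
            n_a, n_b = int(pa.sum()), int(pb.sum())
            tor = (gained + lost) / (n_a + n_b) if (n_a + n_b) > 0 else np.nan
            rows.append((dend, mouse_of[dend], a, b, gained, lost, n_a, n_b, tor))
    per_pair = pd.DataFrame(
        rows,
        columns=["dendrite_id", "mouse_id", "t_i", "t_j", "gained", "lost", "n_ti", "n_tj", "tor"],
    )
    return TurnoverResult(per_pair=per_pair)


@dataclass
class SurvivalCurve:
    """Cohort survival fractions plus spine-level event records."""

    cohort: str
    per_dendrite: pd.DataFrame  # dendrite_id, mouse_id, time_days, n_at_risk, sf
    mouse_mean: pd.DataFrame  # time_days, sf (unweighted mean of per-mouse curves)
    events: pd.DataFrame  # spine_id, dendrite_id, mouse_id, time_days, status

    def pooled(self) -> pd.DataFrame:
        """Cohort-pooled SF over all spines (all dendrites together)."""
        ev = self.events
        rows = []
        for t in sorted(self.per_dendrite["time_days"].unique()):
            # spines observable to relative time t
            obs = ev[ev["horizon_days"] >= t]
            n0 = len(obs)
            lost = ((obs["status"] == "event") & (obs["time_days"] <= t)).sum()
            if n0:
                rows.append((t, n0, 1.0 - lost / n0))
        return pd.DataFrame(rows, columns=["time_days", "n_at_risk", "sf"])


def survival_fraction(
    fm: FateMatrix, cohort: Literal["day0", "new"] = "day0"
) -> SurvivalCurve:
    """Survival fraction of the day-0 or newly-formed spine cohort.

    For ``cohort="day0"`` time runs from each dendrite's first session; for
    ``cohort="new"`` each spine's clock starts at its first-present session.
    SF at relative time t is computed among cohort spines whose dendrite was
    still being imaged t days after their entry (the observable set), so
    censored spines never count as losses.
    """
    mouse_of = fm.mouse_of()
    event_rows = []
    for dend in fm.dendrites:
        piv = fm.presence(dend)
        days = np.asarray(piv.columns, dtype=float)
        if len(days) < 2:
            continue
        arr = piv.to_numpy().astype(bool)
        first_present = np.where(
            arr.any(axis=1), arr.argmax(axis=1), -1
        )
        for i, spine in enumerate(piv.index):
            fp = first_present[i]
            if fp < 0:
                continue
            if cohort == "day0":
                if fp != 0:
                    continue
                entry_idx = 0
            else:
                if fp == 0:
                    continue
                entry_idx = fp
            entry_day = days[entry_idx]
            # absorbing loss: first absent session after entry
            later = np.flatnonzero(~arr[i, entry_idx:])
            horizon = days[-1] - entry_day
            if later.size:
                t_event = days[entry_idx + later[0]] - entry_day
                event_rows.append(
                    (spine, dend, mouse_of[dend], t_event, "event", entry_day, horizon)
                )
            else:
                event_rows.append(
                    (spine, dend, mouse_of[dend], horizon, "censored", entry_day, horizon)
                )
    events = pd.DataFrame(
        event_rows,
        columns=["spine_id", "dendrite_id", "mouse_id", "time_days", "status", "entry_day", "horizon_days"],
    )
    if events.empty:
        raise ValueError(f"no spines in cohort {cohort!r}")

    def _curve(ev: pd.DataFrame, times: np.ndarray) -> pd.DataFrame:
        rows = []
        for t in times:
            obs = ev[ev["horizon_days"] >= t]
            n0 = len(obs)
            if n0 == 0:
                continue
            lost = ((obs["status"] == "event") & (obs["time_days"] <= t)).sum()
            rows.append((t, n0, 1.0 - lost / n0))
        return pd.DataFrame(rows, columns=["time_days", "n_at_risk", "sf"])

    all_times = np.unique(
        np.concatenate(
            [events["time_days"].to_numpy(), events["horizon_days"].to_numpy(), [0.0]]
        )
    )
    per_dend = []
    for dend, ev in events.groupby("dendrite_id"):
        c = _curve(ev, all_times)
        c.insert(0, "mouse_id", mouse_of[dend])
        c.insert(0, "dendrite_id", dend)
        per_dend.append(c)
    per_dendrite = pd.concat(per_dend, ignore_index=True)

    per_mouse = []
    for mouse, ev in events.groupby("mouse_id"):
        c = _curve(ev, all_times)
        c["mouse_id"] = mouse
        per_mouse.append(c)
    mouse_mean = (
        pd.concat(per_mouse, ignore_index=True)
        .groupby("time_days")["sf"]
        .mean()
        .reset_index()
    )
    return SurvivalCurve(
        cohort=cohort, per_dendrite=per_dendrite, mouse_mean=mouse_mean, events=events
    )
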