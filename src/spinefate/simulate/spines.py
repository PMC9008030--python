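"""Simulate longitudinal spine cohorts with mixture-exponential lifetimes.

The generator mirrors the statistical structure assumed by the dynamics and
survival analyses: each day-0 spine belongs to a fast- or slow-decaying
population with an exponentially distributed lifetime; imaging discretizes
those continuous lifetimes onto an observation schedule; and, when
homeostatic gains are enabled, new spines are born in each inter-session
interval at a rate that matches the expected number of losses, keeping the
expected spine count constant over time.

Defaults correspond to the published VIP survival decomposition
S(t) = 0.59 e^(-0.13 t) + 0.42 e^(-0.02 t), with the mixing weights
normalized to sum to one (0.59 + 0.42 = 1.01; survival at t = 0 must be 1),
16 dendrites in 5 mice observed on a 4-day grid up to day 54.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .._rng import substream
from ..dynamics import FateMatrix

__all__ = ["SpineSimParams", "simulate_spine_cohort", "mixture_survival"]

#: Published VIP two-exponential amplitudes and decay rates (per day).
VIP_AMPLITUDES = (0.59, 0.42)
VIP_RATES = (0.13, 0.02)
#: Published pyramidal (L2/3) counterpart; the slow rate prints as 0.00 and is
#: represented by a small positive hazard (lifetimes must be finite).
PYR_AMPLITUDES = (0.16, 0.84)
PYR_RATES = (0.21, 0.001)


def mixture_survival(t, fast_fraction: float, fast_rate: float, slow_rate: float):
    """Analytic survival of the two-class exponential-lifetime mixture."""
    t = np.asarray(t, dtype=float)
    return fast_fraction * np.exp(-fast_rate * t) + (1.0 - fast_fraction) * np.exp(
        -slow_rate * t
    )


@dataclass
class SpineSimParams:
    """Parameters of the spine-cohort generator.

    ``fast_fraction`` is the mixing weight of the fast-decaying class (the
    slow class has weight ``1 - fast_fraction``); ``fast_rate`` and
    ``slow_rate`` are per-day hazards. ``new_spine_mix`` optionally overrides
    (fast_fraction, fast_rate, slow_rate) for spines born after day 0;
    by default new spines share the day-0 mixture.
    """

    fast_fraction: float = VIP_AMPLITUDES[0] / sum(VIP_AMPLITUDES)
    fast_rate: float = VIP_RATES[0]
    slow_rate: float = VIP_RATES[1]
    gain_mode: bool = True
    new_spine_mix: Optional[tuple[float, float, float]] = None
    n_dendrites: int = 16
    spines_per_dendrite: Optional[int] = None
    n_mice: int = 5
    schedule: Sequence[float] = field(default_factory=lambda: tuple(range(0, 55, 4)))
    density_per_um: float = 0.75
    dendrite_length_um: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.fast_fraction <= 1.0:
            raise ValueError("fast_fraction must lie in [0, 1]")
        if self.fast_rate <= 0 or self.slow_rate <= 0:
            raise ValueError("hazard rates must be positive")
        sched = np.asarray(self.schedule, dtype=float)
        if sched.size == 0:
            raise ValueError("observation schedule is empty")
        if sched[0] != 0 or np.any(np.diff(sched) <= 0):
            raise ValueError("schedule must be strictly increasing and start at 0")
        if self.new_spine_mix is not None:
            f, rf, rs = self.new_spine_mix
            if not 0.0 <= f <= 1.0 or rf <= 0 or rs <= 0:
                raise ValueError("invalid new_spine_mix")
        if self.n_dendrites < 1 or self.n_mice < 1:
            raise ValueError("need at least one dendrite and one mouse")
        if self.spines_per_dendrite is None and (
            self.density_per_um <= 0 or self.dendrite_length_um <= 0
        ):
            raise ValueError("density_per_um and dendrite_length_um must be positive")

    @property
    def n_initial_spines(self) -> int:
        if self.spines_per_dendrite is not None:
            return int(self.spines_per_dendrite)
        return int(round(self.density_per_um * self.dendrite_length_um))


def _draw_lifetimes(rng, n, fast_fraction, fast_rate, slow_rate):
    is_fast = rng.random(n) < fast_fraction
    rates = np.where(is_fast, fast_rate, slow_rate)
    lifetimes = rng.exponential(1.0 / rates)
    return is_fast, lifetimes


def simulate_spine_cohort(params: SpineSimParams) -> tuple[FateMatrix, pd.DataFrame]:
    """Simulate a spine cohort and return (fate matrix, hidden truth table).

    The truth table records, per spine, its dendrite/mouse, class
    (``fast``/``slow``), birth day and continuous lifetime; the fate matrix
    only contains the discretized presence/absence observations, exactly as a
    longitudinal imaging experiment would.
    """
    params.validate()
    sched = np.asarray(params.schedule, dtype=float)
    truth_rows = []
    obs_rows = []
    lengths = {}

    mix_new = params.new_spine_mix or (
        params.fast_fraction,
        params.fast_rate,
        params.slow_rate,
    )

    for d in range(params.n_dendrites):
        rng = substream(params.seed, "spine_cohort", f"dendrite{d}")
        mouse = d % params.n_mice
        dendrite_id = f"d{d:03d}"
        mouse_id = f"m{mouse:02d}"
        lengths[dendrite_id] = float(params.dendrite_length_um)

        n0 = params.n_initial_spines
        is_fast, lifetimes = _draw_lifetimes(
            rng, n0, params.fast_fraction, params.fast_rate, params.slow_rate
        )
        births = np.zeros(n0)

        if params.gain_mode:
            # births per interval with expectation equal to the expected
            # number of losses among spines alive at the interval start
            # (memoryless hazards make that expectation exact).
            f_new, rf_new, rs_new = mix_new
            for t0, t1 in zip(sched[:-1], sched[1:]):
                alive = (births <= t0) & (births + lifetimes > t0)
                rates = np.where(is_fast, params.fast_rate, params.slow_rate)
                dt = t1 - t0
                exp_loss = np.sum(1.0 - np.exp(-rates[alive] * dt))
                # newborns may die before the next session; inflate the birth
                # count so the expected number of gains OBSERVED at t1 equals
                # the expected losses, keeping the observed count stationary
                p_surv = sum(
                    w * (1.0 - np.exp(-r * dt)) / (r * dt)
                    for w, r in ((f_new, rf_new), (1.0 - f_new, rs_new))
                )
                n_new = rng.poisson(exp_loss / p_surv)
                if n_new:
                    new_births = rng.uniform(t0, t1, n_new)
                    nf, nl = _draw_lifetimes(rng, n_new, *mix_new)
                    births = np.concatenate([births, new_births])
                    lifetimes = np.concatenate([lifetimes, nl])
                    is_fast = np.concatenate([is_fast, nf])

        deaths = births + lifetimes
        present = (births[:, None] <= sched[None, :]) & (deaths[:, None] > sched[None, :])
        ever_seen = present.any(axis=1)

        for i in np.flatnonzero(ever_seen):
            spine_id = f"{dendrite_id}s{i:04d}"
            truth_rows.append(
                (
                    mouse_id,
                    dendrite_id,
                    spine_id,
                    "fast" if is_fast[i] else "slow",
                    births[i],
                    lifetimes[i],
                )
            )
            for j, day in enumerate(sched):
                obs_rows.append(
                    (mouse_id, dendrite_id, spine_id, float(day), int(present[i, j]))
                )

    obs = pd.DataFrame(
        obs_rows, columns=["mouse_id", "dendrite_id", "spine_id", "session_day", "present"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["mouse_id", "dendrite_id", "spine_id", "class", "birth_day", "lifetime_days"],
    )
    fm = FateMatrix(observations=obs, dendrite_length_um=pd.Series(lengths, name="length_um"))
    return fm, truth
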