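"""Intrinsic and synaptic electrophysiology metric extraction.

Metric definitions (current clamp unless noted):

* sag: |minimum voltage during a hyperpolarizing step minus the steady
  state|, the steady state being the mean over the last 20% of the step;
* rebound: maximum post-step depolarization above the resting baseline;
* action potentials: detected where dV/dt exceeds a threshold slope
  (default 20 mV/ms); amplitude = peak minus the threshold-crossing
  voltage; AHP = most hyperpolarized voltage below the AP threshold during
  repolarization; ADP/DAP = the subsequent local maximum;
* ISIs from consecutive AP peaks; the first ISI at rheobase is the burst
  metric; accommodation index = mean(ISI 2..4) / mean(last 3 ISIs);
* passive properties (voltage clamp, -10 mV step): bi-exponential fit of
  the capacitive transient (tau_fast <= tau_slow), capacitance = transient
  charge / |dV|, input resistance = dV / steady-state current change;
* EPSC metrics (voltage clamp at -70 mV): template-free threshold
  detection of inward events, per-cell average event, 10-90% rise time via
  linear interpolation.

All voltage metrics are differences, hence invariant to baseline offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Sweep",
    "sag_and_rebound",
    "detect_aps_and_shape",
    "passive_properties",
    "epsc_metrics",
    "compare_groups",
]


@dataclass
class Sweep:
    """Uniformly sampled sweep with step-protocol metadata."""

    time_ms: np.ndarray
    signal: np.ndarray
    units: str = "mV"
    step_on_ms: float = 0.0
    step_off_ms: float = 0.0
    baseline_ms: tuple[float, float] = (0.0, 0.0)
    delta_v_mv: float = 0.0
    event_times_ms: Optional[np.ndarray] = None

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_ms.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        steps = np.diff(self.time_ms)
        if steps.size and not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("sampling must be uniform")

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    def window(self, t0: float, t1: float) -> np.ndarray:
        m = (self.time_ms >= t0) & (self.time_ms < t1)
        return self.signal[m]


def sag_and_rebound(sweep: Sweep) -> tuple[float, float]:
    """(sag, rebound) in the sweep's units for a hyperpolarizing step."""
    if sweep.step_off_ms <= sweep.step_on_ms:
        raise ValueError("sweep carries no step metadata")
    t0, t1 = sweep.step_on_ms, sweep.step_off_ms
    during = sweep.window(t0, t1)
    if during.size == 0:
        raise ValueError("empty step window")
    steady = float(np.mean(sweep.window(t1 - 0.2 * (t1 - t0), t1)))
    sag = abs(float(during.min()) - steady)
    post = sweep.signal[sweep.time_ms >= t1]
    if post.size == 0:
        return sag, np.nan
    base0, base1 = sweep.baseline_ms
    baseline = (
        float(np.mean(sweep.window(base0, base1))) if base1 > base0 else float(sweep.signal[0])
    )
    rebound = abs(float(post.max()) - baseline)
    return sag, rebound


@dataclass
class APReport:
    ap_times_ms: np.ndarray
    amplitude_mv: float
    threshold_mv: float
    ahp_mv: float
    adp_mv: float
    isis_ms: np.ndarray
    first_isi_ms: float
    accommodation_index: float
    n_aps: int = field(init=False)

    def __post_init__(self):
        self.n_aps = len(self.ap_times_ms)


def detect_aps_and_shape(sweep: Sweep, dvdt_threshold: float = 20.0) -> APReport:
    """Detect APs and report shape/timing metrics (missing values = NaN).

    ``dvdt_threshold`` is the detection slope in mV/ms.
    """
    v = sweep.signal
    t = sweep.time_ms
    dt = sweep.dt_ms
    dvdt = np.gradient(v, dt)
    above = dvdt > dvdt_threshold
    onsets = np.flatnonzero(above & ~np.roll(above, 1))
    onsets = onsets[onsets > 0]

    peaks, thresholds = [], []
    for k, on in enumerate(onsets):
        end = onsets[k + 1] if k + 1 < len(onsets) else len(v)
        seg = v[on:end]
        if seg.size == 0:
            continue
        peaks.append(on + int(np.argmax(seg)))
        thresholds.append(v[on])
    peaks = np.asarray(peaks, dtype=int)

    if peaks.size == 0:
        return APReport(
            ap_times_ms=np.array([]),
            amplitude_mv=np.nan,
            threshold_mv=np.nan,
            ahp_mv=np.nan,
            adp_mv=np.nan,
            isis_ms=np.array([]),
            first_isi_ms=np.nan,
            accommodation_index=np.nan,
        )

    thr0 = float(thresholds[0])
    amp = float(v[peaks[0]] - thr0)

    # AHP / ADP from the repolarization after the first AP
    end = peaks[1] if peaks.size > 1 else len(v)
    seg = v[peaks[0] : end]
    ahp = adp = np.nan
    below = np.flatnonzero(seg < thr0)
    if below.size:
        trough_rel = below[0] + int(np.argmin(seg[below[0] :]))
        ahp = float(thr0 - seg.min())
        tail = seg[trough_rel:]
        if tail.size > 2:
            # subsequent local maximum above the trough
            adp_val = float(tail.max() - seg[trough_rel])
            adp = adp_val if adp_val > 0 else np.nan

    ap_times = t[peaks]
    isis = np.diff(ap_times)
    first_isi = float(isis[0]) if isis.size else np.nan
    if isis.size >= 6:
        acc = float(np.mean(isis[1:4]) / np.mean(isis[-3:]))
    else:
        acc = np.nan
    return APReport(
        ap_times_ms=ap_times,
        amplitude_mv=amp,
        threshold_mv=thr0,
        ahp_mv=ahp,
        adp_mv=adp,
        isis_ms=isis,
        first_isi_ms=first_isi,
        accommodation_index=acc,
    )


@dataclass
class PassiveReport:
    tau_fast_ms: float
    tau_slow_ms: float
    amp_fast_pa: float
    amp_slow_pa: float
    capacitance_pf: float
    input_resistance_mohm: float
    rss: float


def passive_properties(sweep: Sweep) -> PassiveReport:
    """Bi-exponential fit of a voltage-clamp capacitive transient.

    Capacitance is the charge integral of the transient (baseline- and
    steady-state-corrected) divided by |dV|; input resistance is
    dV / (steady-state current change). Components are reported with
    tau_fast <= tau_slow.
    """
    if sweep.delta_v_mv == 0:
        raise ValueError("sweep carries no voltage-step metadata")
    t0 = sweep.step_on_ms
    t = sweep.time_ms
    i = sweep.signal
    base = i[t < t0]
    i0 = float(base.mean()) if base.size else 0.0
    after = t >= t0
    ts = t[after] - t0
    y = i[after] - i0

    span = ts[-1]
    steady = float(np.mean(y[ts > 0.8 * span]))
    trans = y - steady
    a0 = trans[0] if trans.size else 0.0

    def resid(p):
        af, as_, lf, ls = p
        return af * np.exp(-ts / np.exp(lf)) + as_ * np.exp(-ts / np.exp(ls)) - trans

    best = None
    for tf0, ts0 in ((span / 100, span / 10), (span / 300, span / 30), (span / 30, span / 3)):
        try:
            res = least_squares(
                resid, [a0 * 0.8, a0 * 0.2, np.log(tf0), np.log(ts0)], xtol=1e-14, ftol=1e-14
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res.x)
    if best is None:
        raise RuntimeError("bi-exponential fit failed to converge")
    rss, (af, as_, lf, ls) = best
    tf, tsl = float(np.exp(lf)), float(np.exp(ls))
    if tf > tsl:
        tf, tsl, af, as_ = tsl, tf, as_, af

    charge_fc = float(np.trapezoid(trans, ts))  # pA*ms = fC
    cap_pf = abs(charge_fc / sweep.delta_v_mv)  # fC/mV = pF
    rin_mohm = abs(sweep.delta_v_mv / steady) * 1e3 if steady != 0 else np.inf  # mV/pA = GOhm
    return PassiveReport(
        tau_fast_ms=tf,
        tau_slow_ms=tsl,
        amp_fast_pa=float(af),
        amp_slow_pa=float(as_),
        capacitance_pf=cap_pf,
        input_resistance_mohm=rin_mohm,
        rss=rss,
    )


@dataclass
class EpscReport:
    event_times_ms: np.ndarray
    amplitude_pa: float
    frequency_hz: float
    rise_10_90_ms: float
    mean_event: np.ndarray


def _rise_time_10_90(t: np.ndarray, y: np.ndarray) -> float:
    """10-90% rise of a positive-going transient, linear interpolation."""
    peak_idx = int(np.argmax(y))
    peak = y[peak_idx]
    if peak <= 0:
        return np.nan
    rise = y[: peak_idx + 1]
    tt = t[: peak_idx + 1]

    def crossing(level):
        above = np.flatnonzero(rise >= level)
        if above.size == 0:
            return np.nan
        j = above[0]
        if j == 0:
            return tt[0]
        frac = (level - rise[j - 1]) / (rise[j] - rise[j - 1])
        return tt[j - 1] + frac * (tt[j] - tt[j - 1])

    return float(crossing(0.9 * peak) - crossing(0.1 * peak))


def epsc_metrics(
    sweep: Sweep,
    threshold_pa: float = 4.0,
    window_ms: tuple[float, float] = (2.0, 8.0),
) -> EpscReport:
    """Detect inward synaptic events and summarize amplitude/frequency/rise.

    Events are negative deflections crossing ``threshold_pa`` below
    baseline, with a refractory gap of ``window_ms[0]``; the per-cell mean
    event (a window around each onset) provides the 10-90% rise time.
    """
    i = sweep.signal
    t = sweep.time_ms
    dt = sweep.dt_ms
    base = float(np.median(i))
    dev = base - i  # positive-going deviations for inward events
    above = dev > threshold_pa
    starts = np.flatnonzero(above & ~np.roll(above, 1))
    starts = starts[starts > 0]
    # merge onsets closer than the refractory gap
    events = []
    last = -np.inf
    for s in starts:
        if (s - last) * dt >= window_ms[0]:
            events.append(s)
        last = s
    events = np.asarray(events, dtype=int)

    if events.size == 0:
        duration_s = (t[-1] - t[0]) / 1000.0
        return EpscReport(
            event_times_ms=np.array([]),
            amplitude_pa=np.nan,
            frequency_hz=0.0,
            rise_10_90_ms=np.nan,
            mean_event=np.array([]),
        )

    pre = int(round(window_ms[0] / dt))
    post = int(round(window_ms[1] / dt))
    snippets = []
    amps = []
    for s in events:
        s0, s1 = s - pre, s + post
        if s0 < 0 or s1 > len(i):
            continue
        snip = dev[s0:s1]
        snippets.append(snip)
        amps.append(float(snip.max()))
    mean_event = np.mean(snippets, axis=0) if snippets else np.array([])
    rise = (
        _rise_time_10_90(np.arange(mean_event.size) * dt, mean_event)
        if mean_event.size
        else np.nan
    )
    duration_s = (t[-1] - t[0]) / 1000.0
    return EpscReport(
        event_times_ms=t[events],
        amplitude_pa=float(np.mean(amps)) if amps else np.nan,
        frequency_hz=events.size / duration_s,
        rise_10_90_ms=rise,
        mean_event=mean_event,
    )


def compare_groups(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U comparison of two metric vectors; returns (U, p).

    Exact null distribution when min(n1, n2) <= 8 and there are no ties,
    normal approximation with tie correction otherwise.
    """
    from scipy.stats import mannwhitneyu

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
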