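"""Construct electrophysiology sweeps with exactly known metric values.

Three sweep kinds are supported:

* ``current_step`` - current-clamp hyperpolarizing step with a sag transient
  of exactly the requested amplitude (alpha-function dip whose on-grid peak
  equals the sag) and an optional post-step rebound bump;
* ``vclamp_step``  - voltage-clamp capacitive transient built as a sum of
  two exponentials plus a steady-state current step, so the bi-exponential
  fit, charge-integral capacitance and input resistance have closed-form
  ground truth;
* ``epsc_train``   - alpha-function synaptic events whose 10-90% rise time
  is set exactly by solving the alpha-function shape for the time constant.

Each generator returns a :class:`spinefate.ephys.Sweep`.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .._rng import substream
from ..ephys import Sweep

__all__ = ["simulate_ephys_sweep", "alpha_tau_for_rise"]


def _alpha_shape(x):
    # normalized alpha function x e^{1-x}, peak 1 at x = 1
    return x * np.exp(1.0 - x)


def _alpha_crossing(level: float) -> float:
    """x < 1 where the rising phase of x e^{1-x} crosses ``level``."""
    return brentq(lambda x: _alpha_shape(x) - level, 1e-12, 1.0)


#: rising-phase crossings of the normalized alpha function at 10%/90% of peak
_X10 = _alpha_crossing(0.1)
_X90 = _alpha_crossing(0.9)


def alpha_tau_for_rise(rise_ms: float) -> float:
    """Alpha-function time constant giving a 10-90% rise of ``rise_ms``."""
    return rise_ms / (_X90 - _X10)


def simulate_ephys_sweep(kind: str, truth: dict, seed: int = 0) -> Sweep:
    """Build a sweep whose named metrics equal the requested ground truth.

    ``truth`` keys by kind (all optional unless noted):

    * ``current_step``: ``sag_mv`` (>= 0), ``rebound_mv``, ``v_rest``,
      ``step_mv`` (steady-state deflection), ``step_on_ms``, ``step_off_ms``,
      ``duration_ms``, ``dt_ms``, ``noise_sd``
    * ``vclamp_step``: ``tau_fast_ms``, ``tau_slow_ms``, ``amp_fast_pa``,
      ``amp_slow_pa``, ``delta_i_pa`` (steady-state step), ``charge_fc``
      (overrides amplitudes to yield this total transient charge),
      ``delta_v_mv``, ``step_on_ms``, ``duration_ms``, ``dt_ms``, ``noise_sd``
    * ``epsc_train``: ``rise_ms`` (required), ``amplitude_pa``,
      ``event_times_ms`` or ``frequency_hz``, ``duration_ms``, ``dt_ms``,
      ``noise_sd``
    """
    rng = substream(seed, "ephys_sweep", kind)
    if kind == "current_step":
        return _current_step(truth, rng)
    if kind == "vclamp_step":
        return _vclamp_step(truth, rng)
    if kind == "epsc_train":
        return _epsc_train(truth, rng)
    raise ValueError(f"unknown sweep kind {kind!r}")


def _grid(duration_ms, dt_ms):
    n = int(round(duration_ms / dt_ms)) + 1
    return np.arange(n) * dt_ms


def _on_grid_alpha(t, t0, tau, dt):
    """Alpha transient starting at t0 with its peak exactly on a sample."""
    # shift tau to a multiple of dt so the peak (at t0 + tau) is sampled
    tau = max(round(tau / dt), 1) * dt
    x = np.clip((t - t0) / tau, 0.0, None)
    return _alpha_shape(x), tau


def _current_step(truth, rng):
    sag = float(truth.get("sag_mv", 0.0))
    if sag < 0:
        raise ValueError("sag must be non-negative")
    rebound = float(truth.get("rebound_mv", 0.0))
    v_rest = float(truth.get("v_rest", -70.0))
    step_mv = float(truth.get("step_mv", -15.0))
    t_on = float(truth.get("step_on_ms", 100.0))
    t_off = float(truth.get("step_off_ms", 600.0))
    duration = float(truth.get("duration_ms", 900.0))
    dt = float(truth.get("dt_ms", 0.1))
    t = _grid(duration, dt)

    v = np.full_like(t, v_rest)
    during = (t >= t_on) & (t < t_off)
    v[during] = v_rest + step_mv
    if sag > 0:
        # dip fully decayed before the last 20% of the step
        shape, _ = _on_grid_alpha(t, t_on, (t_off - t_on) / 40.0, dt)
        v -= sag * np.where(during, shape, 0.0)
    if rebound > 0:
        # overshoot above the resting baseline, peaking exactly on a sample
        shape, _ = _on_grid_alpha(t, t_off, (duration - t_off) / 10.0, dt)
        post = t >= t_off
        v[post] = v_rest + rebound * shape[post]
    noise = float(truth.get("noise_sd", 0.0))
    if noise > 0:
        v = v + noise * rng.standard_normal(v.shape)
    return Sweep(
        time_ms=t,
        signal=v,
        units="mV",
        step_on_ms=t_on,
        step_off_ms=t_off,
        baseline_ms=(0.0, t_on),
    )


def _vclamp_step(truth, rng):
    tau_f = float(truth.get("tau_fast_ms", 0.27))
    tau_s = float(truth.get("tau_slow_ms", 2.0))
    if tau_f <= 0 or tau_s <= 0 or tau_f > tau_s:
        raise ValueError("need 0 < tau_fast <= tau_slow")
    a_f = float(truth.get("amp_fast_pa", -400.0))
    a_s = float(truth.get("amp_slow_pa", -80.0))
    delta_v = float(truth.get("delta_v_mv", -10.0))
    if "charge_fc" in truth:
        # scale amplitudes so the transient charge integral is as requested
        q = a_f * tau_f + a_s * tau_s  # pA*ms = fC
        scale = float(truth["charge_fc"]) / q
        a_f, a_s = a_f * scale, a_s * scale
    delta_i = float(truth.get("delta_i_pa", -50.0))
    t_on = float(truth.get("step_on_ms", 10.0))
    duration = float(truth.get("duration_ms", 60.0))
    dt = float(truth.get("dt_ms", 0.01))
    t = _grid(duration, dt)
    i = np.zeros_like(t)
    after = t >= t_on
    ts = t[after] - t_on
    i[after] = a_f * np.exp(-ts / tau_f) + a_s * np.exp(-ts / tau_s) + delta_i
    noise = float(truth.get("noise_sd", 0.0))
    if noise > 0:
        i = i + noise * rng.standard_normal(i.shape)
    return Sweep(
        time_ms=t,
        signal=i,
        units="pA",
        step_on_ms=t_on,
        step_off_ms=duration,
        baseline_ms=(0.0, t_on),
        delta_v_mv=delta_v,
    )


def _epsc_train(truth, rng):
    rise = float(truth["rise_ms"])
    if rise <= 0:
        raise ValueError("rise_ms must be positive")
    amp = float(truth.get("amplitude_pa", 8.0))
    duration = float(truth.get("duration_ms", 1000.0))
    dt = float(truth.get("dt_ms", 0.05))
    if "event_times_ms" in truth:
        ev = np.asarray(truth["event_times_ms"], dtype=float)
    else:
        freq = float(truth.get("frequency_hz", 5.0))
        n_ev = int(round(freq * duration / 1000.0))
        ev = np.sort(rng.uniform(20.0, duration - 20.0, n_ev))
    t = _grid(duration, dt)
    i = np.zeros_like(t)
    tau = alpha_tau_for_rise(rise)
    for t0 in ev:
        x = np.clip((t - t0) / tau, 0.0, None)
        i -= amp * _alpha_shape(x)  # inward (negative) currents
    noise = float(truth.get("noise_sd", 0.0))
    if noise > 0:
        i = i + noise * rng.standard_normal(i.shape)
    return Sweep(
        time_ms=t,
        signal=i,
        units="pA",
        step_on_ms=0.0,
        step_off_ms=duration,
        baseline_ms=(0.0, 0.0),
        event_times_ms=ev,
    )
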