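"""Survival modelling of spine-cohort data.

Implements the model-comparison and regression layer on top of the survival
fractions produced by :mod:`spinefate.dynamics`:

* nonlinear least-squares fits of single (a e^{bt}) and two-exponential-sum
  (a e^{bt} + c e^{dt}) survival functions, with Gaussian-error AIC and the
  finite-sample corrected cAIC = AIC + 2k(k+1)/(n-k-1) for model selection;
* the Kaplan-Meier product-limit estimator with Greenwood confidence bands;
* a Cox proportional-hazards comparison h(x, t) = h0(t) e^{bx} between two
  spine populations with Efron tie handling and Huber-White standard errors
  clustered by mouse;
* a linear mixed-effects trend test for spine density over time (random
  intercepts for mouse and for dendrite nested in mouse).

AIC convention: for least-squares fits the Gaussian log-likelihood gives
AIC = n ln(2 pi RSS / n) + n + 2(k_model + 1), i.e. the error variance
counts as an estimated parameter. The ``k`` reported in results includes it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ExpFitResult",
    "KMEstimate",
    "CoxResult",
    "DensityTrendResult",
    "fit_exponential",
    "caic",
    "kaplan_meier",
    "cox_ph",
    "fit_density_trend",
]


# ---------------------------------------------------------------- exponential fits


@dataclass
class ExpFitResult:
    """Result of an exponential survival fit.

    For ``two_sum`` the components are ordered fast first (b <= d <= 0).
    """

    model: Literal["single", "two_sum"]
    params: tuple  # (a, b) or (a, b, c, d)
    rss: float
    n: int
    k: int  # free parameters including the error variance
    aic: float = field(init=False)
    caic: float = field(init=False)

    def __post_init__(self):
        self.aic, self.caic = caic(rss=self.rss, k=self.k, n=self.n)

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        if self.model == "single":
            a, b = self.params
            return a * np.exp(b * t)
        a, b, c, d = self.params
        return a * np.exp(b * t) + c * np.exp(d * t)


def caic(
    rss: Optional[float] = None,
    loglik: Optional[float] = None,
    k: int = 0,
    n: int = 0,
) -> tuple[float, float]:
    """(AIC, cAIC) from either an RSS (Gaussian errors) or a log-likelihood.

    cAIC adds the finite-sample correction 2k(k+1)/(n-k-1), which requires
    n > k + 1.
    """
    if (rss is None) == (loglik is None):
        raise ValueError("pass exactly one of rss, loglik")
    if n <= k + 1:
        raise ValueError("cAIC undefined for n <= k + 1")
    if rss is not None:
        if rss < 0:
            raise ValueError("RSS must be non-negative")
        rss = max(float(rss), np.finfo(float).tiny)
        loglik = -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)
    aic = -2.0 * loglik + 2.0 * k
    return aic, aic + 2.0 * k * (k + 1) / (n - k - 1)


def _residual_fn(t, sf, model):
    if model == "single":
        return lambda p: p[0] * np.exp(p[1] * t) - sf
    return lambda p: p[0] * np.exp(p[1] * t) + p[2] * np.exp(p[3] * t) - sf


def _amplitudes_at_rates(t, sf, b, d):
    """Least-squares amplitudes for fixed rates (clipped to be >= 0)."""
    X = np.column_stack([np.exp(b * t), np.exp(d * t)])
    coef, *_ = np.linalg.lstsq(X, sf, rcond=None)
    return np.clip(coef, 0.0, None)


def fit_exponential(
    times,
    sf,
    model: Literal["single", "two_sum"] = "two_sum",
) -> ExpFitResult:
    """Fit a e^{bt} (single) or a e^{bt} + c e^{dt} (two_sum) to SF data.

    Constraints: amplitudes >= 0, rates <= 0; the amplitudes are NOT
    constrained to sum to one. The two-exponential fit uses a deterministic
    multistart over a rate grid, with starting amplitudes from a linear
    solve at fixed rates; the best-RSS start wins (first in grid order on
    ties).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(sf, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and sf must be 1-d of equal length")
    # small overshoot allowed: fitted two-exponential curves may exceed 1 at
    # t = 0 (amplitudes are not constrained to sum to one)
    if np.any(y <= 0) or np.any(y > 1.05):
        raise ValueError("survival fractions must lie in (0, 1]")
    k_model = 2 if model == "single" else 4
    if t.size < k_model + 2:
        raise ValueError("need at least k + 2 time points")

    fun = _residual_fn(t, y, model)
    if model == "single":
        b0 = -0.05
        with np.errstate(divide="ignore"):
            pos = y > 0
            if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
                slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
                b0 = min(slope, -1e-9)
        starts = [np.array([max(y.max(), 1e-3), b0])]
        lower, upper = [0.0, -np.inf], [np.inf, 0.0]
    else:
        starts = []
        for b in (-0.5, -0.2, -0.1):
            for d in (-0.05, -0.01, -0.001):
                a0, c0 = _amplitudes_at_rates(t, y, b, d)
                starts.append(np.array([a0, b, c0, d]))
        lower, upper = [0.0, -np.inf, 0.0, -np.inf], [np.inf, 0.0, np.inf, 0.0]

    best = None
    failures = []
    for x0 in starts:
        try:
            res = least_squares(fun, x0, bounds=(lower, upper), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(str(exc))
            continue
        rss = float(np.sum(res.fun**2))
        if res.success and (best is None or rss < best[0] - 1e-15):
            best = (rss, res.x)
    if best is None:
        raise RuntimeError(f"exponential fit failed to converge: {failures}")
    rss, p = best
    if model == "two_sum":
        a, b, c, d = p
        if b > d:  # order fast component first
            a, b, c, d = c, d, a, b
        p = (float(a), float(b), float(c), float(d))
    else:
        p = (float(p[0]), float(p[1]))
    return ExpFitResult(model=model, params=p, rss=rss, n=t.size, k=k_model + 1)


# ---------------------------------------------------------------- Kaplan-Meier


@dataclass
class KMEstimate:
    """Product-limit estimate with Greenwood-based 95% confidence bands."""

    timeline: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    transform: str  # "log" or "plain"

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(
    events: pd.DataFrame,
    transform: Literal["log", "plain"] = "log",
    alpha: float = 0.05,
) -> KMEstimate:
    """Kaplan-Meier estimator from event records (time_days, status).

    ``status`` is ``"event"``/``"censored"`` (or 1/0). Records censored at an
    event time are counted at risk for that event (censoring ordered after
    events at tied times, the standard convention). Confidence bands use the
    Greenwood variance on the log-survival scale by default; ``plain`` gives
    the untransformed Greenwood band.
    """
    from lifelines import KaplanMeierFitter
    from scipy.stats import norm

    if len(events) == 0:
        raise ValueError("no event records")
    times = np.asarray(events["time_days"], dtype=float)
    status = events["status"]
    observed = (
        (status == "event") | (status == 1)
        if status.dtype == object
        else status.astype(bool)
    )
    if np.any(times < 0):
        raise ValueError("event times must be non-negative")

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=np.asarray(observed, dtype=int))
    table = kmf.event_table
    timeline = table.index.to_numpy(dtype=float)
    d = table["observed"].to_numpy(dtype=float)
    n = table["at_risk"].to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index).to_numpy()

    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where((n > 0) & (n > d), d / (n * (n - d)), np.where(d > 0, np.inf, 0.0))
    cumvar = np.cumsum(terms)  # Greenwood variance of log S
    z = norm.ppf(1 - alpha / 2)
    with np.errstate(invalid="ignore"):
        if transform == "log":
            half = z * np.sqrt(cumvar)
            lo = surv * np.exp(-half)
            hi = np.minimum(surv * np.exp(half), 1.0)
        else:
            se = surv * np.sqrt(cumvar)
            lo = np.clip(surv - z * se, 0.0, 1.0)
            hi = np.clip(surv + z * se, 0.0, 1.0)
    lo = np.where(surv == 0, 0.0, np.nan_to_num(lo, nan=0.0))
    hi = np.where(surv == 0, 0.0, hi)
    return KMEstimate(
        timeline=timeline, survival=surv, ci_lower=lo, ci_upper=hi, transform=transform
    )


# ---------------------------------------------------------------- Cox PH


@dataclass
class CoxResult:
    """Two-group Cox proportional-hazards fit, robust errors clustered by mouse."""

    b: float
    se_naive: float = np.nan
    se_robust: float = np.nan
    z: float = np.nan
    p: float = np.nan
    reference: str = ""
    comparison: str = ""
    n_events: int = 0

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.b))


def cox_ph(
    events: pd.DataFrame,
    group_col: str = "group",
    cluster_col: str = "mouse_id",
    reference: Optional[str] = None,
) -> CoxResult:
    """Cox PH comparison of two groups with Efron ties and clustered errors.

    ``events`` needs columns ``time_days``, ``status`` and the group/cluster
    columns. ``reference`` names the level coded 0 (default: first sorted
    level); the coefficient b is the log hazard ratio of the other level.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError
    from scipy.stats import norm

    levels = sorted(events[group_col].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    if reference is None:
        reference = levels[0]
    other = [g for g in levels if g != reference][0]

    df = pd.DataFrame(
        {
            "time": np.asarray(events["time_days"], dtype=float),
            "event": (
                (events["status"] == "event") | (events["status"] == 1)
            ).astype(int).to_numpy(),
            "x": (events[group_col].astype(str) == other).astype(float).to_numpy(),
            "cluster": events[cluster_col].to_numpy(),
        }
    )
    for g, lvl in ((0.0, reference), (1.0, other)):
        if df.loc[df["x"] == g, "event"].sum() == 0:
            raise ValueError(f"group {lvl!r} has no events")

    def _fit(robust, cluster):
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col="time",
                event_col="event",
                cluster_col=cluster,
                robust=robust,
                formula="x",
            )
        return cph

    try:
        plain = _fit(robust=False, cluster=None)
        clustered = _fit(robust=True, cluster="cluster")
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox fit did not converge (separation?): {exc}") from exc

    b = float(clustered.params_["x"])
    se_r = float(clustered.standard_errors_["x"])
    se_n = float(plain.standard_errors_["x"])
    z = b / se_r
    p = 2 * norm.sf(abs(z))
    return CoxResult(
        b=b,
        se_naive=se_n,
        se_robust=se_r,
        z=z,
        p=p,
        reference=reference,
        comparison=other,
        n_events=int(df["event"].sum()),
    )


# ---------------------------------------------------------------- density trend


@dataclass
class DensityTrendResult:
    slope: float
    se: float
    stat: float
    df: float
    p: float
    method: str
    ci: tuple[float, float]


def fit_density_trend(density: pd.DataFrame) -> DensityTrendResult:
    """Mixed-effects test of a time trend in spine density.

    Fits density ~ time with random intercepts for mouse and for dendrite
    nested in mouse (REML), and reports a Wald t-test on the time slope with
    containment degrees of freedom df = N - (#dendrites) - 2. With a single
    dendrite the model degenerates; an ordinary regression is used instead
    (with a warning).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from scipy.stats import t as t_dist

    d = density.rename(columns={"density_per_um": "y", "session_day": "day"}).copy()
    n_dend = d["dendrite_id"].nunique()
    if n_dend < 2:
        warnings.warn("single dendrite: falling back to ordinary regression")
        X = sm.add_constant(d["day"].to_numpy())
        fit = sm.OLS(d["y"].to_numpy(), X).fit()
        slope, se = fit.params[1], fit.bse[1]
        df = fit.df_resid
        method = "OLS fallback"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "y ~ day",
                data=d,
                groups="mouse_id",
                re_formula="1",
                vc_formula={"dendrite": "0 + C(dendrite_id)"},
            )
            fit = model.fit(reml=True)
        slope = float(fit.params["day"])
        se = float(fit.bse["day"])
        df = max(len(d) - n_dend - 2, 1)
        method = "MixedLM REML, Wald t with containment df"
    stat = slope / se
    p = 2 * t_dist.sf(abs(stat), df)
    half = t_dist.ppf(0.975, df) * se
    return DensityTrendResult(
        slope=float(slope),
        se=float(se),
        stat=float(stat),
        df=float(df),
        p=float(p),
        method=method,
        ci=(float(slope - half), float(slope + half)),
    )
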