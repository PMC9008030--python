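"""Exponential fits + cAIC selection, Kaplan-Meier, Cox PH and the density
trend model, each checked against hand computations or independent oracles."""

import numpy as np
import pandas as pd
import pytest

from spinefate.simulate import SpineSimParams, simulate_spine_cohort
from spinefate.dynamics import survival_fraction
from spinefate.survival import (
    CoxResult,
    caic,
    cox_ph,
    fit_density_trend,
    fit_exponential,
    kaplan_meier,
)

T_GRID = np.arange(0.0, 56.0, 4.0)


# ---------------------------------------------------------------- exponential


class TestFitExponential:
    def test_single_exact_recovery(self):
        y = 1.0 * np.exp(-0.1 * T_GRID)
        fit = fit_exponential(T_GRID, y, "single")
        assert fit.params[0] == pytest.approx(1.0, abs=1e-6)
        assert fit.params[1] == pytest.approx(-0.1, abs=1e-6)

    def test_two_sum_recovers_published_vip_curve(self):
        y = 0.59 * np.exp(-0.13 * T_GRID) + 0.42 * np.exp(-0.02 * T_GRID)
        fit = fit_exponential(T_GRID, y, "two_sum")
        assert np.allclose(fit.params, (0.59, -0.13, 0.42, -0.02), atol=1e-4)

    def test_nested_rss_monotone(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            y = np.clip(np.exp(-0.08 * T_GRID) + 0.03 * rng.standard_normal(T_GRID.size), 1e-3, 1.0)
            r1 = fit_exponential(T_GRID, y, "single").rss
            r2 = fit_exponential(T_GRID, y, "two_sum").rss
            assert r2 <= r1 + 1e-10

    def test_fast_component_ordered_first(self):
        y = 0.3 * np.exp(-0.5 * T_GRID) + 0.7 * np.exp(-0.01 * T_GRID)
        fit = fit_exponential(T_GRID, y, "two_sum")
        assert fit.params[1] <= fit.params[3] <= 0

    def test_rejects_bad_sf(self):
        with pytest.raises(ValueError):
            fit_exponential(T_GRID, np.full(T_GRID.size, 1.5), "single")
        with pytest.raises(ValueError):
            fit_exponential([0, 1, 2], [1, 0.5, 0.2], "two_sum")  # too few points


class TestCaic:
    def test_correction_arithmetic(self):
        aic, c = caic(rss=1.0, k=2, n=6)
        assert c - aic == pytest.approx(4.0)
        aic, c = caic(rss=1.0, k=3, n=13)
        assert c - aic == pytest.approx(24 / 9)

    def test_requires_enough_observations(self):
        with pytest.raises(ValueError):
            caic(rss=1.0, k=5, n=6)

    def test_converges_to_aic_for_large_n(self):
        aic, c = caic(loglik=-100.0, k=4, n=10**5)
        assert c - aic < 1e-3

    def test_caic_exceeds_aic(self):
        aic, c = caic(rss=0.5, k=3, n=10)
        assert c > aic

    @pytest.mark.parametrize(
        "gen_model,select,min_rate",
        [("two_sum", "two_sum", 0.90), ("single", "single", 0.80)],
    )
    def test_model_selection_rates(self, gen_model, select, min_rate):
        """cAIC prefers the generating model in most noisy replicates."""
        rng = np.random.default_rng(12)
        t = np.arange(0.0, 56.0, 4.0)  # 14 points
        if gen_model == "two_sum":
            truth = 0.59 * np.exp(-0.13 * t) + 0.42 * np.exp(-0.02 * t)
        else:
            truth = 1.0 * np.exp(-0.05 * t)
        wins = 0
        n_rep = 200
        for _ in range(n_rep):
            y = np.clip(truth + 0.03 * rng.standard_normal(t.size), 1e-3, 1.04)
            fits = {m: fit_exponential(t, y, m) for m in ("single", "two_sum")}
            if min(fits, key=lambda m: fits[m].caic) == select:
                wins += 1
        assert wins / n_rep >= min_rate


# ---------------------------------------------------------------- Kaplan-Meier


def naive_product_limit(times, observed):
    """Brute-force product over risk sets (independent oracle)."""
    times = np.asarray(times, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    event_times = np.unique(times[observed])
    surv = {}
    s = 1.0
    for t in event_times:
        at_risk = np.sum(times >= t)
        deaths = np.sum((times == t) & observed)
        s *= 1.0 - deaths / at_risk
        surv[t] = s
    return surv


class TestKaplanMeier:
    def test_hand_product_limit(self):
        ev = pd.DataFrame(
            {"time_days": [4, 8, 8, 8], "status": ["event", "event", "censored", "censored"]}
        )
        km = kaplan_meier(ev)
        assert km.at(4) == pytest.approx(0.75)
        assert km.at(8) == pytest.approx(0.50)

    def test_no_events_gives_unit_curve(self):
        ev = pd.DataFrame({"time_days": [4, 8], "status": ["censored", "censored"]})
        km = kaplan_meier(ev)
        assert np.allclose(km.survival, 1.0)
        assert np.allclose(km.ci_lower, 1.0) and np.allclose(km.ci_upper, 1.0)

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(10, 40).round(1)
        ev = pd.DataFrame({"time_days": times, "status": "event"})
        km = kaplan_meier(ev)
        for t, s in zip(km.timeline, km.survival):
            assert s == pytest.approx(np.mean(times > t))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        times = rng.integers(1, 10, n).astype(float)
        observed = rng.random(n) < 0.7
        ev = pd.DataFrame(
            {"time_days": times, "status": np.where(observed, "event", "censored")}
        )
        km = kaplan_meier(ev)
        oracle = naive_product_limit(times, observed)
        for t, s in oracle.items():
            assert km.at(t) == pytest.approx(s, abs=1e-12)

    def test_ci_transforms_bracket_estimate(self):
        ev = pd.DataFrame(
            {"time_days": [2, 4, 6, 8, 8], "status": ["event"] * 3 + ["censored"] * 2}
        )
        for transform in ("log", "plain"):
            km = kaplan_meier(ev, transform=transform)
            assert np.all(km.ci_lower <= km.survival + 1e-12)
            assert np.all(km.ci_upper >= km.survival - 1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            kaplan_meier(pd.DataFrame({"time_days": [], "status": []}))


# ---------------------------------------------------------------- Cox PH


def cox_partial_loglik(b, times, events, x):
    """Partial log-likelihood with Breslow ties (oracle is used tie-free)."""
    ll = 0.0
    for i in np.flatnonzero(events):
        at_risk = times >= times[i]
        ll += b * x[i] - np.log(np.sum(np.exp(b * x[at_risk])))
    return ll


def golden_section_max(f, lo, hi, tol=1e-10):
    phi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    while abs(b - a) > tol:
        if f(c) > f(d):
            b, d = d, c
            c = b - phi * (b - a)
        else:
            a, c = c, d
            d = a + phi * (b - a)
    return (a + b) / 2


def exp_group_events(rate_a, rate_b, n, seed, cluster_sizes=4):
    rng = np.random.default_rng(seed)
    rows = []
    for grp, rate in (("A", rate_a), ("B", rate_b)):
        t = rng.exponential(1.0 / rate, n)
        for i, ti in enumerate(t):
            rows.append((f"{grp}{i}", grp, f"{grp}_m{i % cluster_sizes}", ti, "event"))
    return pd.DataFrame(rows, columns=["spine_id", "group", "mouse_id", "time_days", "status"])


class TestCox:
    def test_hazard_ratio_accessor(self):
        assert CoxResult(b=1.95).hazard_ratio == pytest.approx(7.028, abs=0.01)

    def test_rate_doubling_recovers_log2(self):
        ev = exp_group_events(1.0, 2.0, 2000, seed=3)
        res = cox_ph(ev, reference="A")
        assert abs(res.b - np.log(2)) < 2.5 * res.se_robust

    def test_null_case_small_z(self):
        hits = 0
        for seed in range(10):
            ev = exp_group_events(1.0, 1.0, 200, seed=seed)
            res = cox_ph(ev, reference="A")
            hits += abs(res.b) < 2 * res.se_robust
        assert hits >= 8

    def test_matches_golden_section_oracle_without_ties(self):
        rng = np.random.default_rng(9)
        n = 60
        times = rng.exponential(1.0, n)
        times += np.arange(n) * 1e-9  # enforce uniqueness
        x = (rng.random(n) < 0.5).astype(float)
        ev = pd.DataFrame(
            {
                "spine_id": range(n),
                "group": np.where(x > 0, "B", "A"),
                "mouse_id": [f"m{i}" for i in range(n)],
                "time_days": times,
                "status": "event",
            }
        )
        res = cox_ph(ev, reference="A")
        b_oracle = golden_section_max(
            lambda b: cox_partial_loglik(b, times, np.ones(n, bool), x), -3, 3
        )
        assert res.b == pytest.approx(b_oracle, abs=1e-4)

    def test_singleton_clusters_match_hc_robust(self):
        """With one observation per cluster the clustered sandwich equals the
        heteroskedasticity-consistent robust SE."""
        from lifelines import CoxPHFitter

        ev = exp_group_events(1.0, 2.0, 80, seed=5, cluster_sizes=80)
        res = cox_ph(ev, reference="A")
        df = pd.DataFrame(
            {
                "time": ev["time_days"],
                "event": 1,
                "x": (ev["group"] == "B").astype(float),
            }
        )
        cph = CoxPHFitter()
        cph.fit(df, "time", "event", robust=True)
        assert res.se_robust == pytest.approx(float(cph.standard_errors_["x"]), rel=1e-6)

    def test_one_group_without_events_rejected(self):
        ev = exp_group_events(1.0, 1.0, 10, seed=0)
        ev.loc[ev["group"] == "B", "status"] = "censored"
        with pytest.raises(ValueError):
            cox_ph(ev, reference="A")


# ---------------------------------------------------------------- density trend


def stationary_density_table(seed, n_dendrites=16, n_mice=5, noise_sd=0.05):
    rng = np.random.default_rng(seed)
    days = np.arange(0.0, 56.0, 4.0)
    rows = []
    for d in range(n_dendrites):
        mouse = f"m{d % n_mice}"
        level = 0.75 + 0.17 * rng.standard_normal() + 0.05 * rng.standard_normal()
        for day in days:
            rows.append((mouse, f"d{d}", day, level + noise_sd * rng.standard_normal()))
    return pd.DataFrame(rows, columns=["mouse_id", "dendrite_id", "session_day", "density_per_um"])


class TestDensityTrend:
    def test_exact_recovery_of_deterministic_slope(self):
        days = np.arange(0.0, 20.0, 4.0)
        rows = [
            (f"m{d % 2}", f"d{d}", day, 0.5 + 0.01 * day + 0.1 * d)
            for d in range(4)
            for day in days
        ]
        df = pd.DataFrame(rows, columns=["mouse_id", "dendrite_id", "session_day", "density_per_um"])
        res = fit_density_trend(df)
        assert res.slope == pytest.approx(0.01, abs=1e-6)

    def test_stationary_coverage_at_study_scale(self):
        """16 dendrites / 5 mice with iid session noise: time effect is
        non-significant and the slope CI covers zero in most replicates."""
        covered = nonsig = 0
        n_seeds = 20
        for seed in range(n_seeds):
            res = fit_density_trend(stationary_density_table(seed))
            covered += res.ci[0] <= 0 <= res.ci[1]
            nonsig += res.p > 0.05
        assert covered >= int(0.9 * n_seeds)
        assert nonsig >= int(0.9 * n_seeds)

    def test_single_dendrite_falls_back_to_ols(self):
        df = stationary_density_table(0, n_dendrites=1, n_mice=1)
        with pytest.warns(UserWarning, match="single dendrite"):
            res = fit_density_trend(df)
        assert res.method == "OLS fallback"


# ---------------------------------------------------------------- integration


def test_mouse_averaged_fit_prefers_two_exponentials():
    """A cohort simulated from the published two-exponential decomposition is
    classified as two-population by cAIC on the mouse-averaged SF."""
    p = SpineSimParams(gain_mode=False, n_dendrites=16, spines_per_dendrite=120, seed=2)
    fm, _ = simulate_spine_cohort(p)
    mm = survival_fraction(fm, "day0").mouse_mean
    keep = mm["sf"] > 0
    fits = {
        m: fit_exponential(mm.loc[keep, "time_days"], mm.loc[keep, "sf"], m)
        for m in ("single", "two_sum")
    }
    assert fits["two_sum"].caic < fits["single"].caic
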