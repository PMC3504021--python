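"""Survival statistics against hand-computed and simulation oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from crlmsig.survival import (
    baseline_comparison,
    bh_adjust,
    classification_metrics,
    cox_fit,
    fisher_exact_p,
    km_estimate,
    logrank_power,
    logrank_test,
)


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_all_events_is_product_limit():
    km = km_estimate([1, 2, 3], [1, 1, 1])
    assert np.allclose(km["survival"], [2 / 3, 1 / 3, 0.0])
    assert list(km["at_risk"]) == [3, 2, 1]


def test_km_no_events_stays_at_one():
    km = km_estimate([5, 9, 13], [0, 0, 0])
    assert np.allclose(km["survival"], 1.0)


def test_km_censoring_decrements_at_risk_without_a_drop():
    # censored at t=1 before the first event at t=2
    km = km_estimate([1, 2, 3], [0, 1, 1])
    s = km.set_index("time")["survival"]
    assert s.loc[1.0] == 1.0  # no drop at the censoring time
    assert np.isclose(s.loc[2.0], 0.5)  # 2 at risk, 1 event


def test_km_equals_empirical_survival_without_censoring():
    rng = np.random.default_rng(0)
    t = rng.exponential(10, 40).round(1)
    km = km_estimate(t, np.ones(40))
    emp = [(t > u).mean() for u in km["time"]]
    assert np.allclose(km["survival"], emp)


def test_km_negative_time_rejected():
    with pytest.raises(ValueError):
        km_estimate([-1, 2], [1, 1])


# ---------------------------------------------------------------------------
# log-rank


def _logrank_chi2_oracle(time, event, group):
    """Hand computation: sum over event times of hypergeometric increments."""
    time, event, group = map(np.asarray, (time, event, group))
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def test_logrank_identical_groups_gives_zero():
    t = [3, 5, 7, 9]
    e = [1, 0, 1, 1]
    res = logrank_test(t + t, e + e, [0] * 4 + [1] * 4, compute_hr=False)
    assert res.chi_square == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_matches_hand_oracle_on_toy():
    t = [2, 4, 5, 7, 9, 12]
    e = [1, 1, 0, 1, 1, 0]
    g = [0, 1, 0, 1, 0, 1]
    res = logrank_test(t, e, g, compute_hr=False)
    assert res.chi_square == pytest.approx(_logrank_chi2_oracle(t, e, g), rel=1e-9)


def test_logrank_invariant_to_time_rescaling_and_label_swap():
    rng = np.random.default_rng(1)
    t = rng.exponential(12, 50)
    e = (rng.random(50) < 0.7).astype(int)
    g = (rng.random(50) < 0.5).astype(int)
    a = logrank_test(t, e, g, compute_hr=False)
    b = logrank_test(t * 30.44, e, g, compute_hr=False)  # months -> days
    c = logrank_test(t, e, 1 - g, compute_hr=False)
    assert a.chi_square == pytest.approx(b.chi_square, rel=1e-9)
    assert a.p_value == pytest.approx(c.p_value, rel=1e-9)


def test_logrank_single_group_rejected():
    with pytest.raises(ValueError):
        logrank_test([1, 2, 3], [1, 1, 1], [0, 0, 0])


# ---------------------------------------------------------------------------
# Cox regression


def test_cox_binary_covariate_matches_logrank_hr():
    rng = np.random.default_rng(2)
    g = np.repeat([0, 1], 30)
    t = rng.exponential(np.where(g == 1, 6.0, 12.0))
    e = (rng.random(60) < 0.8).astype(int)
    res = logrank_test(t, e, g)
    fit = cox_fit(pd.DataFrame({"time": t, "event": e, "x": g}), ["x"])
    assert res.hazard_ratio == pytest.approx(float(fit.loc["x", "hr"]), abs=1e-3)


def test_cox_univariate_then_auto_screening():
    rng = np.random.default_rng(3)
    n = 120
    x1 = rng.normal(0, 1, n)  # true effect
    x2 = rng.normal(0, 1, n)  # noise
    t = rng.exponential(np.exp(-0.9 * x1) * 10)
    df = pd.DataFrame({"time": t, "event": np.ones(n, int), "x1": x1, "x2": x2})
    uni = cox_fit(df, ["x1", "x2"], mode="univariate")
    assert uni.loc["x1", "p"] < 0.01
    auto = cox_fit(df, ["x1", "x2"], mode="auto")
    assert "x1" in auto.index


def test_cox_constant_covariate_rejected():
    df = pd.DataFrame({"time": [1, 2, 3], "event": [1, 1, 0], "x": [1, 1, 1]})
    with pytest.raises(ValueError):
        cox_fit(df, ["x"])


def test_cox_degenerate_input_is_graceful_error():
    df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 0], "x": [0, 1]})
    with pytest.raises((ValueError, RuntimeError)):
        cox_fit(df, ["x"])


# ---------------------------------------------------------------------------
# log-rank power (Schoenfeld approximation)


def test_power_no_effect_limit():
    assert logrank_power(1.0, 100) == pytest.approx(0.025, abs=1e-6)


def test_power_monotone_in_events_and_effect():
    assert logrank_power(2.0, 100) > logrank_power(2.0, 50)
    assert logrank_power(3.0, 80) > logrank_power(2.0, 80)
    assert logrank_power(0.5, 80) == pytest.approx(logrank_power(2.0, 80), rel=1e-9)


def _simulated_logrank_power(hr, d, n_rep, seed, alpha=0.05):
    """Monte-Carlo rejection rate of the log-rank test: d patients,
    half per arm, no censoring, exponential times with rate ratio hr."""
    rng = np.random.default_rng(seed)
    crit = sps.chi2.ppf(1 - alpha, 1)
    g = np.repeat([0, 1], d // 2)
    rej = 0
    for _ in range(n_rep):
        t = rng.exponential(1.0 / np.where(g == 1, hr, 1.0))
        rej += _logrank_chi2_vec(t, g) > crit
    return rej / n_rep


def _logrank_chi2_vec(t, g):
    """All-events log-rank statistic, O(n log n) (oracle helper)."""
    order = np.argsort(t)
    gs = g[order]
    n = len(t)
    n_at = n - np.arange(n)
    n1_at = (gs[::-1].cumsum()[::-1])
    o_minus_e = (gs - n1_at / n_at).sum()
    keep = n_at > 1  # untied event times: the (n-d)/(n-1) factor is 1
    var = ((n1_at / n_at) * (1 - n1_at / n_at))[keep].sum()
    return o_minus_e**2 / var


def test_power_matches_simulation():
    approx = logrank_power(2.0, 88, 0.5, 0.05)
    sim = _simulated_logrank_power(2.0, 88, n_rep=10_000, seed=4)
    assert approx == pytest.approx(sim, abs=0.03)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def test_bh_step_up_collapses_linear_ps():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)


def test_bh_single_p_unchanged_and_bounds():
    assert bh_adjust([0.2])[0] == pytest.approx(0.2)
    rng = np.random.default_rng(5)
    p = rng.random(100)
    adj = bh_adjust(p)
    assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# baseline comparison & classification metrics


def test_baseline_comparison_reproduces_known_2x2():
    # 45/27 treated in the high class, 19/28 in the low class
    n_high, n_low = 72, 47
    clin = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n_high + n_low)],
            "neoadjuvant": [1] * 45 + [0] * 27 + [1] * 19 + [0] * 28,
            "age": 60.0,
        }
    )
    labels = pd.Series(
        ["high"] * n_high + ["low"] * n_low, index=clin["patient_id"].to_numpy()
    )
    out = baseline_comparison(clin, labels, categorical=["neoadjuvant"], continuous=[])
    expected = fisher_exact_p([[45, 19], [27, 28]])
    assert out.set_index("variable").loc["neoadjuvant", "p"] == pytest.approx(expected)


def test_baseline_comparison_excludes_missing_and_tests_continuous():
    clin = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(12)],
            "margin": ["R0"] * 4 + ["R1"] * 4 + ["missing"] * 4,
            "age": list(range(40, 52)),
        }
    )
    labels = pd.Series(["high", "low"] * 6, index=clin["patient_id"].to_numpy())
    out = baseline_comparison(
        clin, labels, categorical=["margin"], continuous=["age"]
    ).set_index("variable")
    assert out.loc["margin", "n_missing"] == 4
    u = sps.mannwhitneyu(
        clin["age"][labels.to_numpy() == "high"],
        clin["age"][labels.to_numpy() == "low"],
        alternative="two-sided",
    ).pvalue
    assert out.loc["age", "p"] == pytest.approx(float(u))


def test_classification_metrics_enumeration():
    pred = ["high", "high", "low", "low", "high", "low", "high", "low", "high", "low"]
    true = ["high", "low", "low", "high", "high", "low", "low", "low", "high", "unlabelable"]
    m = classification_metrics(pred, true)
    assert m["n_evaluated"] == 9 and m["n_unlabelable"] == 1
    assert m["confusion"] == {"tp": 3, "tn": 3, "fp": 2, "fn": 1}
    assert m["accuracy"] == pytest.approx(6 / 9)
    assert m["sensitivity"] == pytest.approx(3 / 4)
    assert m["specificity"] == pytest.approx(3 / 5)


def test_all_high_predictions_have_unit_sensitivity_zero_specificity():
    m = classification_metrics(["high"] * 6, ["high", "low"] * 3)
    assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0
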