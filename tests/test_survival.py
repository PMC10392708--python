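"""Kaplan-Meier, log-rank, Youden/median cutpoints, Efron Cox."""

import numpy as np
import pandas as pd
import pytest

from tilscore import (cox_univariate, dichotomize, evaluate_marker, km_estimate,
                      logrank_test, youden_cutpoint)
from tilscore.survival import ConvergenceError
from tests.conftest import efron_loglik_reference


# ------------------------------------------------------------------ KM
def test_km_no_censoring_is_empirical_survival():
    km = km_estimate([1, 2, 3], [1, 1, 1])
    np.testing.assert_allclose(km["survival"], [2 / 3, 1 / 3, 0.0])


def test_km_all_censored_stays_at_one():
    km = km_estimate([1, 2, 3], [0, 0, 0])
    np.testing.assert_allclose(km["survival"], 1.0)


def test_km_matches_hand_product_limit():
    # t: 1(e) 2(c) 2(e) 3(e) 4(c) 5(e)
    km = km_estimate([1, 2, 2, 3, 4, 5], [1, 0, 1, 1, 0, 1])
    # S(1)=5/6; S(2)=5/6*4/5=2/3; S(3)=2/3*2/3=4/9; S(5)=4/9*0=0
    expected = {1.0: 5 / 6, 2.0: 2 / 3, 3.0: 4 / 9, 4.0: 4 / 9, 5.0: 0.0}
    for _, row in km.iterrows():
        assert row["survival"] == pytest.approx(expected[row["time"]], abs=1e-12)
    assert km["survival"].is_monotonic_decreasing
    assert km["n_at_risk"].is_monotonic_decreasing


# ------------------------------------------------------------- log-rank
def test_logrank_worked_fixture():
    chi2, p = logrank_test([1, 2, 3, 4], [1, 1, 1, 1], [0, 0, 1, 1])
    assert chi2 == pytest.approx(49 / 17, abs=1e-12)  # O=2, E=5/6, Var=17/36


def test_logrank_identical_copies_null():
    times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
    events = [1, 0, 1, 1, 0, 1]
    group = [0, 0, 0, 1, 1, 1]
    chi2, p = logrank_test(times, events, group)
    assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)


def test_logrank_label_swap_invariant(rng):
    times = rng.exponential(10, size=30)
    events = rng.integers(0, 2, size=30)
    events[0] = 1
    group = rng.integers(0, 2, size=30)
    group[:2] = [0, 1]
    a = logrank_test(times, events, group)[0]
    b = logrank_test(times, events, 1 - group)[0]
    assert a == pytest.approx(b, abs=1e-12)


def test_logrank_no_events_warns():
    with pytest.warns(UserWarning):
        chi2, p = logrank_test([1, 2], [0, 0], [0, 1])
    assert p == 1.0


def test_logrank_matches_lifelines(rng):
    from lifelines.statistics import logrank_test as ll_logrank
    times = rng.exponential(10, size=40)
    events = rng.integers(0, 2, size=40)
    events[:2] = 1
    group = rng.integers(0, 2, size=40)
    group[:2] = [0, 1]
    chi2, p = logrank_test(times, events, group)
    ref = ll_logrank(times[group == 0], times[group == 1],
                     events[group == 0], events[group == 1])
    assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
    assert p == pytest.approx(ref.p_value, rel=1e-9)


# ----------------------------------------------------------- cutpoints
def test_youden_perfect_separation():
    res = youden_cutpoint([1.0, 2.0, 5.0, 6.0], [1, 1, 0, 0])
    assert res.j_statistic == pytest.approx(1.0)
    assert res.cutoff == pytest.approx(3.5)
    assert res.direction == "low"  # events sit below the cutoff
    assert list(res.groups) == ["low", "low", "high", "high"]


def test_youden_matches_exhaustive_search(rng):
    marker = rng.normal(size=25)
    event = rng.integers(0, 2, size=25)
    event[:2] = [0, 1]
    res = youden_cutpoint(marker, event)
    n_pos, n_neg = event.sum(), (1 - event).sum()
    best = 0.0
    distinct = np.unique(marker)
    for cut in (distinct[:-1] + distinct[1:]) / 2:
        high = marker > cut
        j = abs((high & (event == 1)).sum() / n_pos
                + (~high & (event == 0)).sum() / n_neg - 1.0)
        best = max(best, j)
    assert res.j_statistic == pytest.approx(best, abs=1e-12)


def test_youden_monotone_transform_preserves_grouping(rng):
    marker = pd.Series(rng.normal(size=20))
    event = rng.integers(0, 2, size=20)
    event[:2] = [0, 1]
    a = youden_cutpoint(marker, event)
    b = youden_cutpoint(np.exp(marker), event)
    pd.testing.assert_series_equal(a.groups, b.groups)


def test_youden_degenerate_inputs():
    with pytest.raises(ValueError):
        youden_cutpoint([1.0, 1.0, 1.0], [1, 0, 1])  # single distinct value
    with pytest.raises(ValueError):
        youden_cutpoint([1.0, 2.0, 3.0], [1, 1, 1])  # one class empty


def test_youden_recovers_planted_threshold(rng):
    marker = rng.uniform(0, 10, size=60)
    cut_true = 4.0
    event = (marker < cut_true).astype(int)
    res = youden_cutpoint(marker, event)
    below = marker[marker < cut_true].max()
    above = marker[marker >= cut_true].min()
    assert below < res.cutoff < above
    assert res.j_statistic == pytest.approx(1.0)


def test_median_split_convention():
    res = dichotomize(pd.Series([1.0, 2.0, 3.0, 4.0]), "median")
    assert list(res.groups) == ["low", "low", "high", "high"]
    assert res.cutoff == pytest.approx(2.5)
    with pytest.raises(ValueError):
        dichotomize(pd.Series([3.0, 3.0, 3.0]), "median")  # degenerate split


# ---------------------------------------------------------------- Cox
def test_cox_symmetry_forces_zero_beta():
    beta, hr, se, p = cox_univariate([1, 1, 2, 2], [1, 1, 1, 1], [0, 1, 0, 1])
    assert beta == pytest.approx(0.0, abs=1e-8)
    assert hr == pytest.approx(1.0, abs=1e-8)


def test_cox_matches_grid_search_oracle(rng):
    # oracle: direct maximization of an independent Efron log-likelihood
    times = rng.exponential(5, size=10)
    events = np.array([1, 1, 0, 1, 1, 0, 1, 1, 1, 0])
    x = rng.normal(size=10)
    beta, *_ = cox_univariate(times, events, x)
    grid = np.linspace(beta - 0.5, beta + 0.5, 10001)
    lls = [efron_loglik_reference(b, times, events, x) for b in grid]
    assert abs(grid[int(np.argmax(lls))] - beta) < 1e-4


def test_cox_matches_lifelines(rng):
    from lifelines import CoxPHFitter
    times = rng.exponential(5, size=40)
    events = rng.integers(0, 2, size=40)
    events[:3] = 1
    x = rng.normal(size=40)
    beta, hr, se, p = cox_univariate(times, events, x)
    df = pd.DataFrame({"T": times, "E": events, "x": x})
    cph = CoxPHFitter().fit(df, duration_col="T", event_col="E")
    assert beta == pytest.approx(cph.params_["x"], abs=1e-5)
    assert se == pytest.approx(cph.standard_errors_["x"], abs=1e-5)


def test_cox_rescaling_covariate(rng):
    times = rng.exponential(5, size=30)
    events = rng.integers(0, 2, size=30)
    events[:3] = 1
    x = rng.normal(size=30)
    b1, _, _, p1 = cox_univariate(times, events, x)
    b2, _, _, p2 = cox_univariate(times, events, 4.0 * x)
    assert b2 == pytest.approx(b1 / 4.0, rel=1e-5)
    assert p2 == pytest.approx(p1, rel=1e-5)


def test_cox_degenerate_inputs():
    with pytest.raises(ValueError):
        cox_univariate([1, 2, 3], [1, 1, 0], [2.0, 2.0, 2.0])  # constant
    # perfect separation: high covariate -> strictly earlier events
    times = [1, 2, 3, 10, 11, 12]
    events = [1, 1, 1, 1, 1, 1]
    x = [1, 1, 1, 0, 0, 0]
    with pytest.raises(ConvergenceError):
        cox_univariate(times, events, x)


# --------------------------------------------------- three-way report
def test_evaluate_marker_emits_consistent_row(rng):
    n = 60
    marker = pd.Series(rng.normal(size=n))
    times = rng.exponential(10 * np.exp(0.8 * marker.to_numpy()))
    events = rng.integers(0, 2, size=n)
    events[:3] = 1
    res = evaluate_marker(marker, times, events, name="m", endpoint="bcr")
    assert set(res.logrank) == {"youden", "median"}
    assert set(res.cutpoints) == {"youden", "median"}
    assert res.cox_hr == pytest.approx(np.exp(res.cox_beta))
    for curve in res.km_curves.values():
        assert curve["survival"].is_monotonic_decreasing
        assert curve["n_at_risk"].is_monotonic_decreasing
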