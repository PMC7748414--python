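"""Learning-curve aggregation, OLS slope fits, criterion rule, group contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lickroc.learning import (
    build_curve,
    compare_slopes,
    criterion_day,
    fit_slope,
    rank_tests,
)
from lickroc.roc import session_aroc
from lickroc.synth import default_profiles, simulate_cohort
from lickroc.trials import BLANK, STIMULUS
from .conftest import make_session, make_trial


def ols_oracle(x, y):
    """Normal-equations OLS: slope, intercept, se_slope."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sxx = np.sum((x - x.mean()) ** 2)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    se = np.sqrt(np.sum(resid**2) / (n - 2) / sxx)
    return slope, intercept, se


def test_fit_slope_exact_linear_series():
    days = np.arange(1, 15)
    fit = fit_slope(days, 0.5 + 0.028 * (days - 1))
    assert fit.slope == pytest.approx(0.028, abs=1e-12)
    assert fit.r2 == pytest.approx(1.0)
    assert fit.p_value < 1e-6


def test_fit_slope_constant_series():
    fit = fit_slope(np.arange(1, 11), np.full(10, 0.7))
    assert fit.slope == pytest.approx(0.0, abs=1e-15)
    assert fit.p_value == pytest.approx(1.0)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=30, deadline=None)
def test_fit_slope_matches_normal_equations(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 25))
    x = np.sort(rng.uniform(0, 20, n))
    y = rng.normal(0.5 + 0.03 * x, 0.05)
    fit = fit_slope(x, y)
    slope, intercept, se = ols_oracle(x, y)
    assert fit.slope == pytest.approx(slope, abs=1e-10)
    assert fit.intercept == pytest.approx(intercept, abs=1e-10)
    assert fit.se_slope == pytest.approx(se, abs=1e-10)


def test_fit_slope_range_and_minimum_points():
    days = np.arange(1, 22)
    vals = np.where(days <= 14, 0.5 + 0.02 * days, 0.78)
    full = fit_slope(days, vals, day_range=(1, 14))
    assert full.n == 14
    with pytest.raises(ValueError):
        fit_slope([1, 2], [0.5, 0.6])


@pytest.mark.parametrize(
    "series, expected",
    [
        ([0.6, 0.81, 0.82, 0.85, 0.90], 5),  # run starts day 2, completes day 5
        ([0.81, 0.82, 0.85, 0.90], 4),
        ([0.5, 0.6, 0.7, 0.79], None),
        ([0.8, 0.8, 0.8, 0.8], None),  # strictly greater than threshold
        ([0.9, 0.9, 0.9, 0.5, 0.9, 0.85, 0.82, 0.99], 8),  # broken run restarts
    ],
)
def test_criterion_day_rule(series, expected):
    assert criterion_day(series) == expected


def test_criterion_day_monotone_in_threshold(rng):
    series = rng.uniform(0.5, 1.0, size=30)
    days = [criterion_day(series, threshold=th) for th in (0.6, 0.7, 0.8, 0.9)]
    last = 0
    for d in days:
        if d is None:
            continue
        assert d >= last
        last = d


def test_compare_slopes_contract():
    a = fit_slope(np.arange(1, 15), 0.5 + 0.03 * np.arange(14)
                  + 0.01 * np.sin(np.arange(14)))
    z0, p0 = compare_slopes(a, a)
    assert z0 == 0.0 and p0 == pytest.approx(1.0)
    b = fit_slope(np.arange(1, 15), 0.5 + 0.015 * np.arange(14)
                  + 0.01 * np.cos(np.arange(14)))
    z, p = compare_slopes(a, b)
    zr, pr = compare_slopes(b, a)
    assert zr == pytest.approx(-z) and pr == pytest.approx(p)
    # z at exactly 1.96 sigma -> p ~ 0.05
    se = np.sqrt(a.se_slope**2 + b.se_slope**2)
    shifted = type(a)(slope=b.slope + 1.96 * se * 0 + a.slope - 1.96 * se,
                      intercept=0, se_slope=b.se_slope, r2=0, p_value=1, n=14)
    z2, p2 = compare_slopes(a, type(a)(slope=a.slope - 1.96 * se, intercept=0,
                                       se_slope=b.se_slope, r2=0, p_value=1, n=14))
    assert z2 == pytest.approx(1.96)
    assert p2 == pytest.approx(0.05, abs=1e-3)


def test_rank_tests():
    u, p = rank_tests([1, 2, 3], [4, 5, 6], paired=False)
    assert u == 0.0  # exhaustive rank oracle: every pair favors b
    with pytest.warns(UserWarning):
        stat, p = rank_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
    assert p == 1.0
    a = [3.0, 1.0, 2.0, 5.0]
    b = [4.0, 2.5, 2.0, 9.0]
    _, p1 = rank_tests(a, b, paired=False)
    _, p2 = rank_tests(a[::-1], b, paired=False)
    assert p1 == pytest.approx(p2)  # permutation invariance within samples
    with pytest.raises(ValueError):
        rank_tests([1, 2, 3], [1, 2], paired=True)


def _session_with_aroc(animal, day, hit_latency, n=40):
    trials = []
    for i in range(n):
        trials.append(make_trial(STIMULUS, [hit_latency], index=i))
    for i in range(n):
        trials.append(make_trial(BLANK, [2.5], index=n + i))
    return make_session(trials, animal_id=animal, day=day)


def test_build_curve_population_mean_and_missing_days():
    # animal a: aROC 1 (all stim licks before all blank licks); animal b: 0.5
    s_a = _session_with_aroc("a", 1, hit_latency=0.5)
    s_b = _session_with_aroc("b", 1, hit_latency=2.5)
    curve = build_curve([s_a, s_b])
    aroc_a = session_aroc(s_a.trials)
    aroc_b = session_aroc(s_b.trials)
    assert curve.aroc[0] == pytest.approx((aroc_a + aroc_b) / 2)
    # day 2 only for animal a -> population falls back to the one animal
    s_a2 = _session_with_aroc("a", 2, hit_latency=0.5)
    curve2 = build_curve([s_a, s_b, s_a2])
    assert curve2.days.tolist() == [1, 2]
    assert curve2.aroc[1] == pytest.approx(aroc_a)
    assert np.isnan(curve2.per_animal["b"].loc[2, "aroc"])


def test_build_curve_single_session_equals_session_metrics():
    s = _session_with_aroc("solo", 3, hit_latency=0.8)
    curve = build_curve([s])
    assert curve.days.tolist() == [3]
    assert curve.aroc[0] == pytest.approx(session_aroc(s.trials))


def test_intact_cohort_curve_nondecreasing_in_expectation(profiles):
    sessions = simulate_cohort(profiles["intact"], n_mice=8, n_days=14,
                               n_trials_per_day=240, seed=2)
    curve = build_curve(sessions)
    # smoothed trend: allow small day-to-day noise but no systematic decrease
    assert curve.aroc[-1] > curve.aroc[0] + 0.2
    assert np.all(np.diff(curve.aroc) > -0.06)
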