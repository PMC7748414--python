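"""Censored-latency aROC against its pairwise oracle, plus windowed SDT metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lickroc.roc import (
    LatencySample,
    UndefinedResultError,
    aroc,
    censored_latencies,
    inter_lick_intervals,
    optimal_window,
    rates_and_dprime,
    variability,
)
from lickroc.trials import BLANK, STIMULUS
from .conftest import make_trial


def sample(values, **kw):
    return LatencySample(np.asarray(values, dtype=float), **kw)


def pairwise_aroc_oracle(stim_vals, blank_vals, bin_s=0.1, window_s=4.0):
    """Exhaustive U-statistic on 100 ms-binned values: wins + half-ties."""
    def to_bin(v):
        if v > window_s + 1e-12:
            return int(round(window_s / bin_s))
        return min(int(np.floor(v / bin_s)), int(round(window_s / bin_s)) - 1)

    s = [to_bin(v) for v in stim_vals]
    b = [to_bin(v) for v in blank_vals]
    total = 0.0
    for x in s:
        for y in b:
            total += 1.0 if x < y else (0.5 if x == y else 0.0)
    return total / (len(s) * len(b))


@pytest.mark.parametrize(
    "stim, blank, expected",
    [
        ([0.5, 1.5], [1.0, 2.0], 0.75),  # 3 wins of 4 pairs
        ([0.5, 4.1], [4.1, 4.1], 0.75),  # 2 wins + 2 half-ties
        ([0.5, 1.5, 2.5], [0.5, 1.5, 2.5], 0.5),  # identical samples
        ([0.2, 0.5, 0.9], [4.1, 4.1], 1.0),  # full separation
    ],
)
def test_aroc_worked_examples(stim, blank, expected):
    assert aroc(sample(stim), sample(blank)) == pytest.approx(expected)


latency_values = st.one_of(
    st.floats(0.0, 4.0), st.just(4.1)  # real latencies or the censor surrogate
)


@given(
    st.lists(latency_values, min_size=1, max_size=50),
    st.lists(latency_values, min_size=1, max_size=50),
)
@settings(max_examples=200, deadline=None)
def test_aroc_equals_pairwise_oracle(stim_vals, blank_vals):
    got = aroc(sample(stim_vals), sample(blank_vals))
    want = pairwise_aroc_oracle(stim_vals, blank_vals)
    assert got == pytest.approx(want, abs=1e-12)
    assert 0.0 <= got <= 1.0


@given(
    st.lists(latency_values, min_size=1, max_size=30),
    st.lists(latency_values, min_size=1, max_size=30),
)
@settings(max_examples=100, deadline=None)
def test_aroc_complement_symmetry(stim_vals, blank_vals):
    a = aroc(sample(stim_vals), sample(blank_vals))
    b = aroc(sample(blank_vals), sample(stim_vals))
    assert a + b == pytest.approx(1.0, abs=1e-12)


def test_aroc_monotone_under_earlier_stimulus_licks(rng):
    blank_vals = rng.uniform(0, 4, size=30)
    stim_vals = rng.uniform(0.5, 4, size=30)
    prev = aroc(sample(stim_vals), sample(blank_vals))
    for shift in (0.1, 0.2, 0.3, 0.4, 0.5):
        cur = aroc(sample(np.maximum(stim_vals - shift, 0)), sample(blank_vals))
        assert cur >= prev - 1e-12
        prev = cur


def test_aroc_empty_sample_errors():
    with pytest.raises(UndefinedResultError):
        aroc(sample([]), sample([1.0]))


def test_censored_latencies_mapping():
    trials = [
        make_trial(STIMULUS, [0.5], index=0),
        make_trial(STIMULUS, [], index=1),  # Miss -> censor
        make_trial(BLANK, [], index=2),
        make_trial(BLANK, [], index=3),
        make_trial(BLANK, [3.999], index=4),  # latency kept raw, unbinned here
        make_trial(STIMULUS, [-0.7, 1.0], index=5),  # aborted, dropped
    ]
    stim, blank = censored_latencies(trials)
    assert stim.values_s.tolist() == [0.5, 4.1]
    assert blank.values_s.tolist() == [4.1, 4.1, 3.999]


@pytest.mark.parametrize(
    "hit, fa, expected",
    [
        (0.9, 0.5, 1.2816),  # normal-quantile oracle
        (0.7, 0.7, 0.0),
        (0.899, 0.816, 0.376),  # pooled early-training constellation
    ],
)
def test_dprime_from_known_rates(hit, fa, expected):
    n = 1000
    trials = []
    i = 0
    for k in range(n):
        licked = k < round(hit * n)
        trials.append(make_trial(STIMULUS, [1.0] if licked else [], index=i))
        i += 1
    for k in range(n):
        licked = k < round(fa * n)
        trials.append(make_trial(BLANK, [1.0] if licked else [], index=i))
        i += 1
    summary = rates_and_dprime(trials, 4.0)
    assert summary.hit_rate == pytest.approx(hit, abs=1e-9)
    assert summary.fa_rate == pytest.approx(fa, abs=1e-9)
    assert summary.d_prime == pytest.approx(expected, abs=5e-4)


def test_dprime_antisymmetric_under_rate_swap():
    a = stats.norm.ppf(0.9) - stats.norm.ppf(0.6)
    n = 200
    def build(hit, fa):
        trials = []
        for k in range(n):
            trials.append(make_trial(STIMULUS, [1.0] if k < hit * n else [], index=k))
        for k in range(n):
            trials.append(make_trial(BLANK, [1.0] if k < fa * n else [], index=n + k))
        return rates_and_dprime(trials, 4.0).d_prime
    assert build(0.9, 0.6) == pytest.approx(-build(0.6, 0.9))
    assert build(0.9, 0.6) == pytest.approx(a, abs=1e-9)


def test_optimal_window_discounts_late_blank_licks(rng):
    # stimulus licks all inside 1 s; blank licks spread over the window
    trials = []
    for i in range(80):
        trials.append(make_trial(STIMULUS, [float(rng.uniform(0.3, 0.99))], index=i))
    for i in range(80):
        trials.append(make_trial(BLANK, [float(rng.uniform(0.3, 3.99))], index=80 + i))
    grid = [0.5, 1.0, 2.0, 4.0]
    w, summary = optimal_window(trials, grid)
    exhaustive = {g: rates_and_dprime(trials, g).d_prime for g in grid}
    assert w == max(exhaustive, key=lambda g: exhaustive[g])
    assert summary.d_prime == pytest.approx(max(exhaustive.values()))
    assert w == 1.0  # smallest grid value covering all stimulus licks


def test_optimal_window_single_and_tie_rules():
    trials = [
        make_trial(STIMULUS, [0.5], index=0),
        make_trial(STIMULUS, [], index=1),
        make_trial(BLANK, [0.5], index=2),
        make_trial(BLANK, [], index=3),
    ]
    w, _ = optimal_window(trials, [2.0])
    assert w == 2.0
    # hit == fa at every window -> d' constant -> shortest window wins
    w, s = optimal_window(trials, [1.0, 2.0, 3.0])
    assert w == 1.0 and s.d_prime == pytest.approx(0.0)


def test_variability_examples_and_scaling(rng):
    assert variability([0.5, 0.5, 0.5]) == 0.0
    assert variability([0.4, 0.6]) == pytest.approx(0.04)
    lat = rng.uniform(0.3, 2.0, size=20)
    assert variability(3.0 * lat) == pytest.approx(3.0 * variability(lat))
    with pytest.raises(UndefinedResultError):
        variability([0.5])


def test_inter_lick_intervals():
    assert inter_lick_intervals([[0.0, 1.3, 2.6]]) == pytest.approx(1.3)
    assert inter_lick_intervals([[0, 1], [0, 2]]) == pytest.approx(1.5)
    with pytest.raises(UndefinedResultError):
        inter_lick_intervals([[0.4], []])
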