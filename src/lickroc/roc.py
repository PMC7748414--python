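"""Censored first-lick-latency ROC statistic and windowed signal-detection metrics.

The central performance measure compares the distribution of first-lick
latencies on stimulus versus blank trials. Trials without an in-window lick
(Misses and Correct Rejections) are retained by assigning them a surrogate
latency just outside the response window (4.1 s for a 4 s window), so that
changes in lick *probability* as well as lick *timing* move the statistic.
Latencies are binned at 100 ms, the censor value gets its own terminal bin,
and the ROC curve is swept over bin edges; the area (aROC) then equals the
rank statistic P(L_stim < L_blank) + 1/2 P(L_stim = L_blank) on binned
values. aROC = 0.5 is chance, 1 is perfect separability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .trials import (
    CR,
    DEFAULT_TIMEOUT_WINDOW_S,
    FA,
    HIT,
    MISS,
    Trial,
    classify_trial,
)

__all__ = [
    "LatencySample",
    "SDTSummary",
    "UndefinedResultError",
    "censored_latencies",
    "aroc",
    "session_aroc",
    "rates_and_dprime",
    "optimal_window",
    "variability",
    "inter_lick_intervals",
]

DEFAULT_CENSOR_S = 4.1
DEFAULT_WINDOW_S = 4.0
DEFAULT_BIN_S = 0.1


class UndefinedResultError(ValueError):
    """Raised when a metric is undefined for the given data (e.g. too few licks)."""


@dataclass
class LatencySample:
    """First-lick latencies of one trial type, with censoring metadata.

    ``values_s`` holds real latencies in [0, ``window_s``] plus the
    ``censor_s`` surrogate for no-lick trials.
    """

    values_s: np.ndarray
    censor_s: float = DEFAULT_CENSOR_S
    window_s: float = DEFAULT_WINDOW_S
    bin_s: float = DEFAULT_BIN_S

    def __post_init__(self) -> None:
        self.values_s = np.asarray(self.values_s, dtype=float)
        if self.censor_s <= self.window_s:
            raise ValueError("censor_s must exceed window_s")
        if self.bin_s <= 0:
            raise ValueError("bin_s must be positive")


@dataclass(frozen=True)
class SDTSummary:
    """Hit/false-alarm rates and d' for one response-window length."""

    hit_rate: float
    fa_rate: float
    d_prime: float
    window_s: float


def censored_latencies(
    trials: Iterable[Trial],
    censor_s: float = DEFAULT_CENSOR_S,
    window_s: float | None = None,
    bin_s: float = DEFAULT_BIN_S,
    pre_stim_timeout_window_s: float = DEFAULT_TIMEOUT_WINDOW_S,
) -> tuple[LatencySample, LatencySample]:
    """Split trials into stimulus/blank censored latency samples.

    Hit and FA latencies pass through unchanged; Misses and CRs are mapped
    to the censor timestamp. Aborted trials are dropped. Returns the
    (stimulus, blank) pair.
    """
    trials = list(trials)
    if not trials:
        raise UndefinedResultError("no trials")
    if window_s is None:
        window_s = trials[0].response_window_s
    stim: list[float] = []
    blank: list[float] = []
    for trial in trials:
        outcome = classify_trial(trial, pre_stim_timeout_window_s)
        if outcome.label == HIT:
            stim.append(outcome.first_lick_latency_s)
        elif outcome.label == MISS:
            stim.append(censor_s)
        elif outcome.label == FA:
            blank.append(outcome.first_lick_latency_s)
        elif outcome.label == CR:
            blank.append(censor_s)
    make = lambda v: LatencySample(np.asarray(v), censor_s, window_s, bin_s)
    return make(stim), make(blank)


def _bin_indices(sample: LatencySample) -> tuple[np.ndarray, int]:
    """Map latencies to 100 ms bin indices; censored values to a terminal bin.

    A latency exactly at the window edge falls in the last in-window bin
    (closed upper bound); only the censor surrogate occupies the terminal bin.
    """
    n_bins = int(round(sample.window_s / sample.bin_s))
    v = sample.values_s
    idx = np.minimum(np.floor(v / sample.bin_s).astype(int), n_bins - 1)
    return np.where(v > sample.window_s + 1e-12, n_bins, idx), n_bins


def aroc(stim: LatencySample, blank: LatencySample) -> float:
    """Area under the ROC curve for censored stimulus vs blank latencies.

    Both samples are binned; the ROC is traced by sweeping a latency
    threshold over bin edges ("stimulus responds earlier" is the positive
    direction) and integrating by trapezoid. The result equals
    P(L_s < L_b) + 1/2 P(L_s = L_b) over all stimulus-blank trial pairs on
    binned values.
    """
    if stim.values_s.size == 0 or blank.values_s.size == 0:
        raise UndefinedResultError("aroc needs non-empty stimulus and blank samples")
    s_idx, n_bins = _bin_indices(stim)
    b_idx, _ = _bin_indices(blank)
    c_s = np.bincount(s_idx, minlength=n_bins + 1).astype(np.int64)
    c_b = np.bincount(b_idx, minlength=n_bins + 1).astype(np.int64)
    # trapezoid over the binned ROC, accumulated exactly in integer counts:
    # area = [#(L_s < L_b) + #(L_s = L_b)/2] / (n_s * n_b)
    cum_s = np.concatenate([[0], np.cumsum(c_s)[:-1]])  # stimulus mass below bin
    wins = int(np.sum(c_b * cum_s))
    ties = int(np.sum(c_b * c_s))
    return (wins + ties / 2.0) / (s_idx.size * b_idx.size)


def session_aroc(
    trials: Iterable[Trial],
    censor_s: float = DEFAULT_CENSOR_S,
    bin_s: float = DEFAULT_BIN_S,
    pre_stim_timeout_window_s: float = DEFAULT_TIMEOUT_WINDOW_S,
) -> float:
    """Convenience: censor latencies of a trial list and return their aROC."""
    stim, blank = censored_latencies(
        trials,
        censor_s=censor_s,
        bin_s=bin_s,
        pre_stim_timeout_window_s=pre_stim_timeout_window_s,
    )
    return aroc(stim, blank)


def rates_and_dprime(
    trials: Iterable[Trial],
    window_s: float,
    pre_stim_timeout_window_s: float = DEFAULT_TIMEOUT_WINDOW_S,
) -> SDTSummary:
    """Hit/FA rates within a truncated response window and the resulting d'.

    A trial counts as a response if its first in-window lick occurred at or
    before ``window_s``. Rates are clipped to [1/(2N), 1 - 1/(2N)] per trial
    type before the normal-quantile transform so d' stays finite.
    """
    stim, blank = censored_latencies(
        trials, pre_stim_timeout_window_s=pre_stim_timeout_window_s
    )
    if stim.values_s.size == 0 or blank.values_s.size == 0:
        raise UndefinedResultError("need at least one stimulus and one blank trial")
    if not 0 < window_s <= stim.window_s:
        raise ValueError(f"window_s {window_s} outside (0, {stim.window_s}]")
    hit = float(np.mean(stim.values_s <= window_s))
    fa = float(np.mean(blank.values_s <= window_s))
    n_s, n_b = stim.values_s.size, blank.values_s.size
    hit_c = float(np.clip(hit, 1 / (2 * n_s), 1 - 1 / (2 * n_s)))
    fa_c = float(np.clip(fa, 1 / (2 * n_b), 1 - 1 / (2 * n_b)))
    d_prime = float(stats.norm.ppf(hit_c) - stats.norm.ppf(fa_c))
    return SDTSummary(hit_rate=hit, fa_rate=fa, d_prime=d_prime, window_s=window_s)


def optimal_window(
    trials: Iterable[Trial],
    grid: Sequence[float] | None = None,
    pre_stim_timeout_window_s: float = DEFAULT_TIMEOUT_WINDOW_S,
) -> tuple[float, SDTSummary]:
    """Search the window grid for the length maximizing d'.

    Lick probability, unlike the latency ROC, depends strongly on how much
    of the response window is counted; shortening the window discounts the
    late spontaneous licks that inflate the false-alarm rate. Ties go to the
    shortest window.
    """
    trials = list(trials)
    if grid is None:
        grid = np.round(np.arange(DEFAULT_BIN_S, DEFAULT_WINDOW_S + 1e-9, DEFAULT_BIN_S), 10)
    grid = list(grid)
    if not grid:
        raise ValueError("empty window grid")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("window grid must be ascending")
    summaries = [
        rates_and_dprime(trials, w, pre_stim_timeout_window_s) for w in grid
    ]
    best = int(np.argmax([s.d_prime for s in summaries]))  # argmax takes first tie
    return float(grid[best]), summaries[best]


def variability(latencies: Sequence[float]) -> float:
    """Trial-to-trial latency variability: sample variance / mean, in seconds.

    Computed on Hit latencies per animal-day (or FA latencies when called on
    blanks). Undefined below two latencies.
    """
    v = np.asarray(latencies, dtype=float)
    if v.size < 2:
        raise UndefinedResultError("variability needs >= 2 latencies")
    return float(np.var(v, ddof=1) / np.mean(v))


def inter_lick_intervals(lick_trains: Iterable[Sequence[float]]) -> float:
    """Mean inter-lick interval pooled over lick trains.

    Successive differences within each ascending train are pooled; trains
    with fewer than two licks contribute nothing. Quantifies spontaneous
    licking rhythm during gray-screen periods.
    """
    diffs: list[np.ndarray] = []
    for train in lick_trains:
        t = np.asarray(train, dtype=float)
        if t.size >= 2:
            if np.any(np.diff(t) <= 0):
                raise ValueError("lick trains must be strictly ascending")
            diffs.append(np.diff(t))
    if not diffs:
        raise UndefinedResultError("no train with >= 2 licks")
    return float(np.mean(np.concatenate(diffs)))
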