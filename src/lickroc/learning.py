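"""Learning curves, linear learning-rate fits, criterion and group contrasts.

Per-animal daily metrics (latency aROC, mean first-lick latency, latency
variability) are averaged unweighted across animals into a population curve.
Learning speed is the OLS slope of aROC against training day; learning is
considered complete on the last day of the first run of four consecutive
sessions with aROC above 0.8. Slopes of different groups are contrasted with
a normal z-test on the slope difference (the "Fisher z-test" reading adopted
here: z = Δslope / sqrt(se_a^2 + se_b^2), two-sided normal p; see the
methods note for why this interpretation was chosen).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import roc as roc_mod
from .roc import UndefinedResultError, variability
from .trials import HIT, Session, classify_trial

__all__ = [
    "LearningCurve",
    "SlopeFit",
    "build_curve",
    "fit_slope",
    "criterion_day",
    "compare_slopes",
    "rank_tests",
]


@dataclass
class LearningCurve:
    """Day-wise population metrics with per-animal detail.

    ``per_animal`` maps animal id -> DataFrame indexed by day with columns
    aroc / fl_latency_s / fl_variability_s (NaN where undefined). Population
    series are unweighted means across animals present on each day.
    """

    days: np.ndarray
    aroc: np.ndarray
    aroc_sem: np.ndarray
    fl_latency_s: np.ndarray
    fl_variability_s: np.ndarray
    per_animal: dict[str, pd.DataFrame]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.days,
                "aroc": self.aroc,
                "aroc_sem": self.aroc_sem,
                "fl_latency_s": self.fl_latency_s,
                "fl_variability_s": self.fl_variability_s,
            }
        )


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of a metric against training day."""

    slope: float
    intercept: float
    se_slope: float
    r2: float
    p_value: float
    n: int


def _session_metrics(session: Session) -> dict[str, float]:
    trials = session.trials
    timeout = session.pre_stim_timeout_window_s
    outcomes = [classify_trial(t, timeout) for t in trials]
    stim, blank = [], []
    window = session.response_window_s
    for o in outcomes:
        if o.label == HIT:
            stim.append(o.first_lick_latency_s)
        elif o.label == "Miss":
            stim.append(roc_mod.DEFAULT_CENSOR_S)
        elif o.label == "FA":
            blank.append(o.first_lick_latency_s)
        elif o.label == "CR":
            blank.append(roc_mod.DEFAULT_CENSOR_S)
    try:
        a = roc_mod.aroc(
            roc_mod.LatencySample(np.asarray(stim), window_s=window),
            roc_mod.LatencySample(np.asarray(blank), window_s=window),
        )
    except UndefinedResultError:
        a = np.nan
    hit_lat = [o.first_lick_latency_s for o in outcomes if o.label == HIT]
    lat = float(np.mean(hit_lat)) if hit_lat else np.nan
    try:
        var = variability(hit_lat)
    except UndefinedResultError:
        var = np.nan
    return {"aroc": a, "fl_latency_s": lat, "fl_variability_s": var}


def build_curve(sessions: Iterable[Session]) -> LearningCurve:
    """Aggregate sessions into per-animal and population learning curves.

    Multiple sessions of one animal on one day are pooled is not expected
    (one session/day by design); if present the first is used. Days missing
    for an animal stay NaN and the population mean is taken over the
    remaining animals.
    """
    sessions = list(sessions)
    if not sessions:
        raise ValueError("no sessions")
    rows = []
    seen = set()
    for s in sessions:
        key = (s.animal_id, s.day)
        if key in seen:
            continue
        seen.add(key)
        rows.append({"animal_id": s.animal_id, "day": s.day, **_session_metrics(s)})
    df = pd.DataFrame(rows)
    days = np.sort(df["day"].unique())
    per_animal = {
        animal: block.set_index("day")[
            ["aroc", "fl_latency_s", "fl_variability_s"]
        ].reindex(days)
        for animal, block in df.groupby("animal_id")
    }
    stack = {m: np.vstack([pa[m].to_numpy() for pa in per_animal.values()])
             for m in ("aroc", "fl_latency_s", "fl_variability_s")}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN day columns
        pop = {m: np.nanmean(v, axis=0) for m, v in stack.items()}
        n_eff = np.sum(~np.isnan(stack["aroc"]), axis=0)
        sem = np.nanstd(stack["aroc"], axis=0, ddof=1) / np.sqrt(
            np.maximum(n_eff, 1)
        )
    return LearningCurve(
        days=days,
        aroc=pop["aroc"],
        aroc_sem=sem,
        fl_latency_s=pop["fl_latency_s"],
        fl_variability_s=pop["fl_variability_s"],
        per_animal=per_animal,
    )


def fit_slope(
    days: Sequence[float],
    values: Sequence[float],
    day_range: tuple[float, float] | None = None,
) -> SlopeFit:
    """OLS fit of values against day over ``day_range`` (inclusive).

    The p-value is the F-test of slope = 0, which for simple regression
    coincides with the two-sided t-test reported by the normal equations.
    """
    d = np.asarray(days, dtype=float)
    v = np.asarray(values, dtype=float)
    mask = np.isfinite(d) & np.isfinite(v)
    if day_range is not None:
        lo, hi = day_range
        mask &= (d >= lo) & (d <= hi)
    d, v = d[mask], v[mask]
    if d.size < 3:
        raise ValueError(f"need >= 3 points in range, got {d.size}")
    res = stats.linregress(d, v)
    p_value = float(res.pvalue)
    if not np.isfinite(p_value):
        # zero residual variance: flat series is maximally null, a perfect
        # sloped line maximally non-null
        p_value = 1.0 if res.slope == 0 else 0.0
    return SlopeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        se_slope=float(res.stderr),
        r2=float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0,
        p_value=p_value,
        n=int(d.size),
    )


def criterion_day(
    aroc_series: Sequence[float],
    threshold: float = 0.8,
    run_length: int = 4,
    days: Sequence[int] | None = None,
) -> int | None:
    """Day on which learning completes: last day of the first run of
    ``run_length`` consecutive sessions with aROC strictly above ``threshold``.

    Returns ``None`` when no such run exists. ``days`` supplies day labels
    (defaults to 1..n).
    """
    v = np.asarray(aroc_series, dtype=float)
    if v.size == 0:
        return None
    labels = np.arange(1, v.size + 1) if days is None else np.asarray(days)
    above = v > threshold
    run = 0
    for i, ok in enumerate(above):
        run = run + 1 if ok else 0
        if run >= run_length:
            return int(labels[i])
    return None


def compare_slopes(fit_a: SlopeFit, fit_b: SlopeFit) -> tuple[float, float]:
    """z-test on the difference of two independent OLS slopes.

    z = (slope_a - slope_b) / sqrt(se_a^2 + se_b^2), two-sided normal p.
    """
    se2 = fit_a.se_slope**2 + fit_b.se_slope**2
    if se2 == 0:
        raise UndefinedResultError("both slope standard errors are zero")
    z = (fit_a.slope - fit_b.slope) / np.sqrt(se2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def rank_tests(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    paired: bool,
) -> tuple[float, float]:
    """Two-sided rank test: Mann-Whitney U (unpaired) or Wilcoxon (paired)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if min(a.size, b.size) < 3:
        raise ValueError("need >= 3 observations per sample")
    if paired:
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        if np.all(a == b):
            warnings.warn("all paired differences are zero; test degenerate")
            return 0.0, 1.0
        res = stats.wilcoxon(a, b, alternative="two-sided")
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
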