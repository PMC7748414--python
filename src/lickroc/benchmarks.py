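"""Headline replication quantities computed from scratch on synthetic cohorts.

These functions re-run the full pipeline (generator -> censored-latency aROC
-> curves/fits) at the study's nominal problem sizes and return the
population quantities the analysis is calibrated to reproduce: the analytic
aROC limits, the early-training (day 4) pooled aROC, the intact cohort's
trained performance / learning slope / latency variability, and the
striatal-projection-ablated cohort's slowed learning. Used by the
reproduction script and the acceptance tests.
"""

from __future__ import annotations

import numpy as np

from . import learning, roc, synth

__all__ = [
    "aroc_identical_samples",
    "aroc_separated_samples",
    "day4_pooled_aroc",
    "learning_cohort_stats",
]


def aroc_identical_samples(seed: int = 0, n: int = 50) -> float:
    """aROC when stimulus and blank latency samples are the same sample."""
    rng = np.random.default_rng(seed)
    values = np.concatenate([rng.uniform(0, 4.0, n - n // 5),
                             np.full(n // 5, roc.DEFAULT_CENSOR_S)])
    s = roc.LatencySample(values)
    return roc.aroc(s, roc.LatencySample(values.copy()))


def aroc_separated_samples(seed: int = 0, n: int = 50) -> float:
    """aROC when every stimulus latency precedes every (censored) blank."""
    rng = np.random.default_rng(seed)
    stim = roc.LatencySample(rng.uniform(0.2, 0.9, n))
    blank = roc.LatencySample(np.full(n, roc.DEFAULT_CENSOR_S))
    return roc.aroc(stim, blank)


def _day4_profile() -> synth.GroupProfile:
    # the printed early-training constellation as a single-day schedule
    return synth.GroupProfile(
        name="day4",
        days=(synth.DaySchedule(
            day=1, q_stim=0.899, mu_stim_s=0.77, cv_stim=0.6,
            q_blank=0.816, mu_blank_s=1.01, cv_blank=0.6,
        ),),
    )


def day4_pooled_aroc(
    seed: int = 0,
    n_cohorts: int = 20,
    n_mice: int = 8,
    n_trials: int = 240,
) -> float:
    """Grand-mean aROC of replicate cohorts run at the day-4 behavior."""
    profile = _day4_profile()
    root = np.random.SeedSequence(seed)
    cohort_means = []
    for cohort_ss in root.spawn(n_cohorts):
        sessions = synth.simulate_cohort(
            profile, n_mice=n_mice, n_days=1, n_trials_per_day=n_trials,
            seed=cohort_ss,
        )
        cohort_means.append(
            np.mean([roc.session_aroc(s.trials) for s in sessions])
        )
    return float(np.mean(cohort_means))


def learning_cohort_stats(
    group: str = "intact",
    seed: int = 0,
    n_rep: int = 20,
    n_mice: int = 8,
    n_days: int = 14,
    n_trials: int = 240,
) -> dict[str, float]:
    """Replicate-averaged learning statistics for one default profile.

    Returns the day 1->14 OLS slope of the population-mean aROC, the day-14
    population aROC, and the day-14 variance/mean of hit latencies, each
    averaged over ``n_rep`` independently seeded cohorts.
    """
    profile = synth.default_profiles()[group]
    root = np.random.SeedSequence(seed)
    slopes, day14, variab = [], [], []
    for cohort_ss in root.spawn(n_rep):
        sessions = synth.simulate_cohort(
            profile, n_mice=n_mice, n_days=n_days, n_trials_per_day=n_trials,
            seed=cohort_ss,
        )
        curve = learning.build_curve(sessions)
        slopes.append(
            learning.fit_slope(curve.days, curve.aroc, day_range=(1, n_days)).slope
        )
        day14.append(float(curve.aroc[curve.days == n_days][0]))
        variab.append(float(curve.fl_variability_s[curve.days == n_days][0]))
    return {
        "slope_aroc_per_day": float(np.mean(slopes)),
        "day14_aroc": float(np.mean(day14)),
        "day14_variability_s": float(np.mean(variab)),
        "n_replicates": n_rep,
        "n_sessions_total": n_rep * n_mice * n_days,
    }
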