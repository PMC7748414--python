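"""Brute-force calibration of the free generator constants.

The day-1 and day-4 schedules and the trained latency mean are pinned by
published population values; the remaining constants (trained blank-lick
probability, latency CVs, and the slow-learning groups' day-14 schedules)
are free. This script simulates replicate cohorts over a small grid of
candidate values and reports, for each candidate, the population anchors the
defaults must reproduce:

  * intact day-14 aROC ~ 0.86 and day 1->14 slope ~ 0.028/day
  * intact day-14 hit-latency variance/mean ~ 0.12 s
  * CSt-ablated day-14 aROC ~ 0.68 and slope ~ 0.014/day

The shipped constants in ``lickroc.synth`` are the grid winners; rerun with
``--grid`` to reproduce the search, or without it to verify the defaults.
"""

from __future__ import annotations

import argparse
from dataclasses import replace

import numpy as np

from lickroc import learning, synth
from lickroc.synth import GroupProfile


def cohort_stats(profile: GroupProfile, n_mice: int, n_rep: int, seed: int = 0):
    """Replicate-averaged day-14 aROC, 1->14 slope, and day-14 variability."""
    ss = np.random.SeedSequence(seed)
    d14, slopes, var = [], [], []
    for rep_ss in ss.spawn(n_rep):
        sessions = synth.simulate_cohort(
            profile, n_mice=n_mice, n_days=14, n_trials_per_day=240, seed=rep_ss
        )
        curve = learning.build_curve(sessions)
        d14.append(curve.aroc[curve.days == 14][0])
        slopes.append(learning.fit_slope(curve.days, curve.aroc, (1, 14)).slope)
        var.append(curve.fl_variability_s[curve.days == 14][0])
    return float(np.mean(d14)), float(np.mean(slopes)), float(np.mean(var))


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--grid", action="store_true", help="run the grid search")
    ap.add_argument("--n-rep", type=int, default=10)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    profiles = synth.default_profiles()
    if not args.grid:
        for name, n_mice in (("intact", 8), ("cst_ablated", 5)):
            d14, slope, var = cohort_stats(profiles[name], n_mice, args.n_rep, args.seed)
            print(f"{name:>12}: day14 aROC {d14:.3f}  slope {slope:.4f}/day  "
                  f"day14 var/mean {var:.3f} s")
        return

    base = profiles["intact"]
    print("intact grid (q_blank14, cv_stim14):")
    for qb in (0.60, 0.64, 0.68, 0.72):
        for cv in (0.44, 0.48, 0.52, 0.56):
            d14 = replace(base.days[2], q_blank=qb, cv_stim=cv)
            prof = replace(base, days=(base.days[0], base.days[1], d14, replace(d14, day=21)))
            stats = cohort_stats(prof, 8, args.n_rep, args.seed)
            print(f"  qb={qb:.2f} cv={cv:.2f} -> d14 {stats[0]:.3f} "
                  f"slope {stats[1]:.4f} var {stats[2]:.3f}")

    cst = profiles["cst_ablated"]
    print("cst grid (q_stim14, q_blank14, mu_stim14):")
    for qs in (0.92, 0.93, 0.94):
        for qb in (0.74, 0.78, 0.82):
            for mu in (0.68, 0.72, 0.78):
                d14 = replace(cst.days[1], q_stim=qs, q_blank=qb, mu_stim_s=mu)
                prof = replace(cst, days=(cst.days[0], d14, cst.days[2]))
                stats = cohort_stats(prof, 5, args.n_rep, args.seed)
                print(f"  qs={qs:.2f} qb={qb:.2f} mu={mu:.2f} -> d14 {stats[0]:.3f} "
                      f"slope {stats[1]:.4f}")


if __name__ == "__main__":
    main()
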