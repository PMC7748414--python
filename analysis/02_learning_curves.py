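"""Learning curves and learning-speed contrasts across groups.

Reads the cohort tables from 01_simulate_cohorts.py, builds day-wise
population aROC / latency / variability curves, fits the day 1-14 learning
slope per group, finds the criterion day (>0.8 aROC for four consecutive
sessions) and contrasts slopes between groups with the z-test on slope
differences. Expected picture: intact and CT-ablated cohorts learn at
~0.028 aROC/day and reach criterion by about day 14, while CSt-ablated
and VC-lesioned cohorts climb at roughly half that rate and stay below
criterion within two weeks.
"""

import json
from pathlib import Path

import pandas as pd

from lickroc import (
    build_curve,
    compare_slopes,
    criterion_day,
    fit_slope,
    read_sessions,
)

IN = Path("results/sessions")
OUT = Path("results")


def main() -> None:
    curves_rows, fits = [], {}
    slope_fits = {}
    for path in sorted(IN.glob("*.csv")):
        group = path.stem
        curve = build_curve(read_sessions(path))
        fit = fit_slope(curve.days, curve.aroc, day_range=(1, 14))
        slope_fits[group] = fit
        crit = criterion_day(curve.aroc, days=curve.days)
        fits[group] = {
            "slope_aroc_per_day": fit.slope,
            "se_slope": fit.se_slope,
            "r2": fit.r2,
            "p_value": fit.p_value,
            "criterion_day": crit,
            "day14_aroc": float(curve.aroc[-1]),
        }
        print(
            f"{group:>18}: slope {fit.slope:+.4f} aROC/day (R2 {fit.r2:.3f}), "
            f"day-14 aROC {curve.aroc[-1]:.3f}, criterion day {crit}"
        )
        df = curve.to_frame()
        df.insert(0, "group", group)
        curves_rows.append(df)
    comparisons = {}
    for a, b in (
        ("cst_ablated", "retro_cre_control"),
        ("ct_ablated", "retro_cre_control"),
        ("vc_lesion", "intact"),
    ):
        if a in slope_fits and b in slope_fits:
            z, p = compare_slopes(slope_fits[a], slope_fits[b])
            comparisons[f"{a}_vs_{b}"] = {"z": z, "p": p}
            print(f"slope contrast {a} vs {b}: z = {z:+.2f}, p = {p:.2g}")
    pd.concat(curves_rows).to_csv(OUT / "learning_curves.csv", index=False)
    (OUT / "learning_fits.json").write_text(
        json.dumps({"fits": fits, "slope_comparisons": comparisons}, indent=2) + "\n"
    )


if __name__ == "__main__":
    main()
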