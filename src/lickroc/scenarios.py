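"""Configuration-driven end-to-end scenarios over synthetic cohorts.

Each scenario composes the generator and the analysis modules into one of
the study's experiment shapes: two-week learning curves across groups,
third-week extended training, pre/post lesion-after-learning comparison,
contrast series with interleaved cortical silencing, a sweep of silencing
impact against training duration, and collicular depth recordings. Outputs
are plain CSV/JSON files under the configured output directory; identical
configurations produce byte-identical summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import learning, neural, psychometrics, roc, synth, trials

__all__ = ["ScenarioConfig", "run_scenario", "summarize", "SCENARIOS"]

SCENARIOS = (
    "learning_14d",
    "extended_21d",
    "prepost_lesion",
    "contrast_silencing",
    "training_duration_sweep",
    "sc_depth",
)


@dataclass
class ScenarioConfig:
    scenario: str
    groups: tuple[str, ...] = ("intact",)
    n_mice: int = 8
    n_days: int = 14
    n_trials: int = 240
    seed: int = 0
    output_dir: str | Path = "results"
    #: number of training stages for the silencing sweep scenario
    n_stages: int = 5

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )
        if min(self.n_mice, self.n_days, self.n_trials) < 1:
            raise ValueError("counts must be >= 1")
        self.groups = tuple(self.groups)

    @classmethod
    def from_mapping(cls, d: Mapping) -> "ScenarioConfig":
        return cls(**{k: d[k] for k in d})


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _curve_records(group: str, curve: learning.LearningCurve) -> list[dict]:
    rows = []
    for i, day in enumerate(curve.days):
        rows.append(
            {
                "group": group,
                "day": int(day),
                "aroc": curve.aroc[i],
                "aroc_sem": curve.aroc_sem[i],
                "fl_latency_s": curve.fl_latency_s[i],
                "fl_variability_s": curve.fl_variability_s[i],
            }
        )
    return rows


def _learning_bundle(cfg: ScenarioConfig, n_days: int) -> dict:
    profiles = synth.default_profiles()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    curve_rows: list[dict] = []
    fits: dict[str, dict] = {}
    all_sessions: list[trials.Session] = []
    curves: dict[str, learning.LearningCurve] = {}
    for group, group_ss in zip(cfg.groups, ss.spawn(len(cfg.groups))):
        sessions = synth.simulate_cohort(
            profiles[group],
            n_mice=cfg.n_mice,
            n_days=n_days,
            n_trials_per_day=cfg.n_trials,
            seed=group_ss,
        )
        all_sessions.extend(sessions)
        curve = learning.build_curve(sessions)
        curves[group] = curve
        curve_rows.extend(_curve_records(group, curve))
        fit14 = learning.fit_slope(curve.days, curve.aroc, day_range=(1, min(14, n_days)))
        entry = {
            "slope": fit14.slope,
            "se_slope": fit14.se_slope,
            "r2": fit14.r2,
            "p_value": fit14.p_value,
            "criterion_day": learning.criterion_day(curve.aroc, days=curve.days),
            "day14_aroc": float(curve.aroc[curve.days == min(14, n_days)][0]),
            "per_animal_slopes": {
                a: learning.fit_slope(pa.index, pa["aroc"], day_range=(1, min(14, n_days))).slope
                for a, pa in curve.per_animal.items()
            },
        }
        if n_days > 14:
            fit_late = learning.fit_slope(curve.days, curve.aroc, day_range=(14, n_days))
            entry["slope_day14_21"] = fit_late.slope
            entry["final_aroc"] = float(curve.aroc[-1])
        fits[group] = entry
    comparisons = {}
    for i, ga in enumerate(cfg.groups):
        for gb in cfg.groups[i + 1:]:
            fa = learning.fit_slope(curves[ga].days, curves[ga].aroc, day_range=(1, min(14, n_days)))
            fb = learning.fit_slope(curves[gb].days, curves[gb].aroc, day_range=(1, min(14, n_days)))
            z, p = learning.compare_slopes(fa, fb)
            comparisons[f"{ga}_vs_{gb}"] = {"z": z, "p": p}
    pd.DataFrame(curve_rows).to_csv(out / "curves.csv", index=False)
    trials.write_sessions(all_sessions, out / "sessions.csv")
    summary = {
        "scenario": cfg.scenario,
        "seed": cfg.seed,
        "groups": list(cfg.groups),
        "fits": fits,
        "slope_comparisons": comparisons,
    }
    _json_dump(summary, out / "summary.json")
    return summary


def _contrast_silencing_bundle(cfg: ScenarioConfig, fold: float | None = None) -> dict:
    profiles = synth.default_profiles()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    group = cfg.groups[0]
    profile = profiles[group]
    if fold is not None:
        profile = replace(profile, silencing_fold=fold)
    results: dict[str, dict] = {}
    curve_rows = []
    per_mouse_folds = []
    for m, mouse_ss in enumerate(ss.spawn(cfg.n_mice)):
        sessions = [
            synth.simulate_session(
                profile,
                day=profile.last_day,
                n_trials=cfg.n_trials,
                p_blank=1.0 / 7.0,
                contrasts=psychometrics.CONTRAST_SERIES_PCT[1:],
                led_fraction=1.0 / 3.0,
                seed=day_ss,
                animal_id=f"{group}_m{m + 1:02d}",
            )
            for day_ss in mouse_ss.spawn(cfg.n_days)
        ]
        fits = {}
        for led in (False, True):
            data = psychometrics.psychometric_data_from_sessions(sessions, led_on=led)
            fits[data.condition] = psychometrics.fit_psychometric(data)
        per_mouse_folds.append(
            psychometrics.threshold_fold_change(
                fits["silenced"].alpha, fits["control"].alpha
            )
        )
        results[f"m{m + 1:02d}"] = {
            cond: {"alpha": f.alpha, "beta": f.beta, "gamma": f.gamma, "lam": f.lam}
            for cond, f in fits.items()
        }
        for cond, f in fits.items():
            for x in np.arange(1.0, 100.5, 1.0):
                curve_rows.append(
                    {"mouse": f"m{m + 1:02d}", "condition": cond,
                     "contrast_pct": x, "aroc": float(f.predict(x))}
                )
    mean_ctrl = float(np.mean([r["control"]["alpha"] for r in results.values()]))
    mean_sil = float(np.mean([r["silenced"]["alpha"] for r in results.values()]))
    summary = {
        "scenario": cfg.scenario,
        "seed": cfg.seed,
        "group": group,
        "threshold_control": mean_ctrl,
        "threshold_silenced": mean_sil,
        "modulation_index": psychometrics.modulation_index(mean_sil, mean_ctrl),
        # fold of group-mean thresholds, matching how a grouped threshold
        # shift is conventionally reported
        "fold_change": psychometrics.threshold_fold_change(mean_sil, mean_ctrl),
        "per_mouse_fold_change": [float(f) for f in per_mouse_folds],
        "per_mouse": results,
    }
    pd.DataFrame(curve_rows).to_csv(out / "psychometric_curves.csv", index=False)
    _json_dump(summary, out / "summary.json")
    return summary


def run_scenario(config: ScenarioConfig) -> dict:
    """Run one end-to-end scenario; returns (and writes) its summary bundle."""
    cfg = config
    print(f"[lickroc] scenario={cfg.scenario} seed={cfg.seed} groups={cfg.groups}")
    if cfg.scenario == "learning_14d":
        return _learning_bundle(cfg, n_days=min(cfg.n_days, 14))
    if cfg.scenario == "extended_21d":
        return _learning_bundle(cfg, n_days=max(cfg.n_days, 21))
    if cfg.scenario == "prepost_lesion":
        return _prepost_bundle(cfg)
    if cfg.scenario == "contrast_silencing":
        return _contrast_silencing_bundle(cfg)
    if cfg.scenario == "training_duration_sweep":
        return _sweep_bundle(cfg)
    if cfg.scenario == "sc_depth":
        return _sc_depth_bundle(cfg)
    raise AssertionError("unreachable")


def _prepost_bundle(cfg: ScenarioConfig) -> dict:
    """Cortical lesion after learning: trained performance is retained.

    'Pre' sessions come from the trained intact schedule; 'post' sessions
    reuse the trained plateau schedule (learning outlasts the cortex), so
    the paired comparison should be null.
    """
    profiles = synth.default_profiles()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    profile = profiles[cfg.groups[0]]
    n_sessions = 4
    pre, post = [], []
    for m, mouse_ss in enumerate(ss.spawn(cfg.n_mice)):
        children = mouse_ss.spawn(2 * n_sessions)
        for k in range(n_sessions):
            pre.append(
                synth.simulate_session(
                    profile, day=profile.last_day, n_trials=cfg.n_trials,
                    seed=children[k], animal_id=f"m{m + 1:02d}",
                )
            )
            post.append(
                synth.simulate_session(
                    profile, day=profile.last_day, n_trials=cfg.n_trials,
                    seed=children[n_sessions + k], animal_id=f"m{m + 1:02d}",
                )
            )
    def per_mouse(sessions):
        vals = {}
        for s in sessions:
            vals.setdefault(s.animal_id, []).append(roc.session_aroc(s.trials))
        return {a: float(np.mean(v)) for a, v in sorted(vals.items())}
    pre_vals, post_vals = per_mouse(pre), per_mouse(post)
    a = [pre_vals[k] for k in pre_vals]
    b = [post_vals[k] for k in pre_vals]
    stat, p = learning.rank_tests(a, b, paired=True)
    summary = {
        "scenario": cfg.scenario,
        "seed": cfg.seed,
        "aroc_pre": float(np.mean(a)),
        "aroc_post": float(np.mean(b)),
        "wilcoxon_statistic": stat,
        "wilcoxon_p": p,
        "per_mouse_pre": pre_vals,
        "per_mouse_post": post_vals,
    }
    _json_dump(summary, out / "summary.json")
    return summary


def _sweep_bundle(cfg: ScenarioConfig) -> dict:
    """Silencing impact versus training duration.

    The generating threshold shift decays from ``silencing_fold`` (early)
    to ``silencing_fold_late`` (prolonged training); sweeping the decay
    stage and re-fitting psychometric pairs should show the modulation
    index declining with training.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    profile = synth.default_profiles()[cfg.groups[0]]
    stages = np.linspace(1.0, 0.0, cfg.n_stages)  # 1 = early, 0 = prolonged
    ss = np.random.SeedSequence(cfg.seed)
    rows = []
    for stage, stage_ss in zip(stages, ss.spawn(len(stages))):
        fold = profile.silencing_fold_late + stage * (
            profile.silencing_fold - profile.silencing_fold_late
        )
        sub = replace(
            cfg, scenario="contrast_silencing",
            output_dir=out / f"stage_{stage:.2f}",
            seed=int(stage_ss.generate_state(1)[0] % 2**31),
        )
        summary = _contrast_silencing_bundle(sub, fold=fold)
        rows.append(
            {
                "training_stage": float(stage),
                "generating_fold": float(fold),
                "modulation_index": summary["modulation_index"],
                "fold_change": summary["fold_change"],
            }
        )
    pd.DataFrame(rows).to_csv(out / "sweep.csv", index=False)
    summary = {"scenario": cfg.scenario, "seed": cfg.seed, "stages": rows}
    _json_dump(summary, out / "summary.json")
    return summary


def _sc_depth_bundle(cfg: ScenarioConfig) -> dict:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    depths = np.arange(100.0, 901.0, 100.0)
    ss = np.random.SeedSequence(cfg.seed)
    stages = {"early": 1.0, "late": 0.2}
    summary: dict = {"scenario": cfg.scenario, "seed": cfg.seed}
    rows = []
    for (label, scale), stage_ss in zip(stages.items(), ss.spawn(len(stages))):
        records = neural.simulate_sc_activity(
            depths, training_scale=scale, n_trials=cfg.n_trials, seed=stage_ss
        )
        d, ctrl, sil = neural.silencing_depth_profile(records)
        for depth, c, s_ in zip(d, ctrl, sil):
            rows.append(
                {"stage": label, "depth_um": depth, "control": c, "silenced": s_}
            )
        # CRF at an intermediate-layer site
        rec = records[int(np.argmax(depths >= 600.0))]
        contrasts, resp = neural.evoked_response(rec, led_on=False)
        fit = neural.fit_crf(contrasts, resp)
        summary[label] = {
            "mean_si_silenced_ratio": float(np.mean(sil[d >= 500.0])),
            "crf": {"r_max": fit.r_max, "n_exp": fit.n_exp, "x50": fit.x50},
        }
    pd.DataFrame(rows).to_csv(out / "depth_profile.csv", index=False)
    _json_dump(summary, out / "summary.json")
    return summary


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.3g}"
    return "NA" if v is None else str(v)


def summarize(bundle: Mapping) -> str:
    """Render a scenario summary as an aligned, human-readable table."""
    lines = [f"scenario: {bundle.get('scenario', 'NA')}  seed: {bundle.get('seed', 'NA')}"]
    def walk(prefix: str, obj) -> None:
        if isinstance(obj, Mapping):
            for k, v in obj.items():
                walk(f"{prefix}{k}.", v) if isinstance(v, Mapping) else lines.append(
                    f"  {prefix}{k:<24} {_fmt(v)}"
                )
        else:
            lines.append(f"  {prefix:<26} {_fmt(obj)}")
    for key, val in bundle.items():
        if key in ("scenario", "seed"):
            continue
        walk(f"{key}." if isinstance(val, Mapping) else f"{key}", val)
    return "\n".join(lines)
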