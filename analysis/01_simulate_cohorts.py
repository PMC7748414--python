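"""Simulate the study cohorts and write their trial tables.

Generates one synthetic cohort per experimental group — intact, retro-Cre
injection control, tectal-projection (CT) ablated, striatal-projection (CSt)
ablated, and full visual-cortex lesion — over 14 daily sessions of ~240
trials, and writes the flat trials CSV for each under results/sessions/.
These tables feed the downstream analysis scripts.
"""

from pathlib import Path

from lickroc import default_profiles, simulate_cohort, write_sessions

SEED = 20201207
OUT = Path("results/sessions")

COHORTS = {  # group -> number of mice, mirroring the study's cohort sizes
    "intact": 8,
    "retro_cre_control": 7,
    "ct_ablated": 5,
    "cst_ablated": 5,
    "vc_lesion": 8,
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    profiles = default_profiles()
    for offset, (group, n_mice) in enumerate(COHORTS.items()):
        sessions = simulate_cohort(
            profiles[group], n_mice=n_mice, n_days=14, n_trials_per_day=240,
            seed=SEED + offset,
        )
        path = OUT / f"{group}.csv"
        write_sessions(sessions, path)
        print(f"{group}: {n_mice} mice x 14 days -> {path}")


if __name__ == "__main__":
    main()
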