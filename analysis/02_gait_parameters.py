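#!/usr/bin/env python
"""Gait-event analysis of the simulated cohort.

For every recording under results/cohort/: synchronize, calibrate against
the standing segment, compute the offset-corrected pitch NAV, detect
per-cycle events and summarize both legs.  Writes one row per subject and
leg to results/gait_parameters.csv and reports group-level means of the
lesion-side (controls: left) leg.
"""

import json
from pathlib import Path

import pandas as pd

from vestigait import PARAMETERS, analyze_recording, read_recording
from vestigait.pipeline import lesion_leg

ROOT = Path(__file__).resolve().parents[1] / "results"
COHORT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"


def main() -> None:
    manifest = json.loads((COHORT / "manifest.json").read_text())
    rows = []
    for entry in manifest:
        recording = read_recording(COHORT / entry["subject"])
        analyses = analyze_recording(recording, with_spectrum=False)
        for leg, a in analyses.items():
            s = a.summary
            rows.append({
                "subject": entry["subject"], "group": entry["group"],
                "leg": leg,
                "lesion_leg": leg == lesion_leg(recording),
                "n_strides": s.n_strides,
                "gait_velocity": s.gait_velocity,
                "var_toeoff_time": s.var_toeoff_time,
                "var_heelstrike_time": s.var_heelstrike_time,
                "share_z": a.median_shares["z"],
                **{p: s.means[p] for p in PARAMETERS}})
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "gait_parameters.csv", index=False)

    lesion = df[df.lesion_leg]
    print("lesion-leg group means (controls: left leg):")
    cols = ["gait_velocity", "n_strides", "stride_time", "stance_time",
            "stance_ratio", "max_nav", "min_nav", "up_slope"]
    print(lesion.groupby("group")[cols].mean().round(3).to_string())
    print(f"\nwrote {ROOT / 'gait_parameters.csv'} ({len(df)} leg-rows)")


if __name__ == "__main__":
    main()
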