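#!/usr/bin/env python
"""Group comparison of the simulated cohort's gait parameters.

Re-analyzes each subject's lesion-side leg (controls: left) and runs the
routed statistical workflow: Lilliefors normality → ANOVA or
Kruskal–Wallis → LSD or Dunnett T3 (Brown–Forsythe decides), with stance
time and stance ratio through Mann–Whitney U + Bonferroni.  Writes the
summary-table-shaped report to results/table1.csv and .json.
"""

import json
from pathlib import Path

from vestigait import build_report, read_recording, report_frame, report_json
from vestigait.pipeline import analyze_series, lesion_leg

ROOT = Path(__file__).resolve().parents[1] / "results"
COHORT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"


def main() -> None:
    manifest = json.loads((COHORT / "manifest.json").read_text())
    summaries = []
    for entry in manifest:
        recording = read_recording(COHORT / entry["subject"])
        leg = lesion_leg(recording)
        analysis = analyze_series(recording.series(leg),
                                  recording.corridor_length,
                                  with_spectrum=False)
        summaries.append((entry["group"], analysis.summary))
    report = build_report(summaries)
    frame = report_frame(report)
    frame.to_csv(ROOT / "table1.csv", index=False)
    (ROOT / "table1.json").write_text(
        json.dumps(report_json(report), indent=2))
    show = ["parameter", "normal_mean", "lvn_mean", "rvn_mean",
            "omnibus", "posthoc"]
    print(frame[show].round(3).to_string(index=False))
    print(f"\nwrote {ROOT / 'table1.csv'} and table1.json")


if __name__ == "__main__":
    main()
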