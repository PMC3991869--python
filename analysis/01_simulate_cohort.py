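#!/usr/bin/env python
"""Simulate the study cohort: 10 control, 5 left-lesion and 5 right-lesion
vestibular-neuritis subjects, each walking the 88.8 m corridor once with
bilateral shank gyroscopes.

Each subject's cycle parameters are drawn around their group's published
column with the published between-subject SDs.  Writes one recording
directory per subject (left.csv, right.csv, meta.yaml) under
scratch/cohort/ (raw signals are bulky and regenerable), plus a cohort
manifest.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np

from vestigait import (cohort_configs, default_params, interpolate_params,
                       sample_subject_params, simulate_walk,
                       write_recording)
from vestigait.pipeline import cohort_label

SEED = 888
OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"


def main() -> None:
    configs = cohort_configs(10, 5, 5, seed=SEED)
    manifest = []
    for i, cfg in enumerate(configs):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 99]))
        if cfg.group == "control":
            p = sample_subject_params("normal", rng)
            cfg = dataclasses.replace(cfg, left_params=p, right_params=p)
        else:
            column = "lvn" if cfg.lesion_side == "left" else "rvn"
            lesion = sample_subject_params(column, rng)
            contra = interpolate_params(
                lesion, default_params("control", "normal"), 0.5)
            left, right = ((lesion, contra) if cfg.lesion_side == "left"
                           else (contra, lesion))
            cfg = dataclasses.replace(cfg, left_params=left,
                                      right_params=right)
        label = cohort_label(cfg)
        subject = f"{label}-{i:02d}"
        recording = simulate_walk(cfg)
        recording.subject_meta["subject"] = subject
        write_recording(recording, OUT / subject)
        manifest.append({"subject": subject, "group": label,
                         "lesion_side": cfg.lesion_side, "seed": cfg.seed,
                         "n_samples": int(recording.left.n)})
        print(f"{subject}: {recording.left.duration:.1f} s per leg")
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"\nwrote {len(manifest)} recordings under {OUT}")


if __name__ == "__main__":
    main()
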