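"""End-to-end orchestration: simulate → calibrate → NAV → events → spectra.

The analysis of one recording proceeds per leg: locate the synchronization
shake, estimate stationary zero offsets from the standing segment just
before it, compute the offset-corrected pitch signal and axis shares,
detect mid-swing peaks and per-cycle events, and aggregate to a walk
summary.  Cohort helpers simulate a set of subjects, analyze the leg of
interest per subject (the lesion-side leg for patients, the left leg for
controls), and feed the group-comparison report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from . import nav as navmod
from . import spectral as spec
from . import stats as statsmod
from .errors import ConfigError
from .io import (AngularVelocitySeries, WalkRecording, detect_sync_start,
                 estimate_offsets, read_recording, write_recording)
from .simulate import SimulationConfig, simulate_walk

log = logging.getLogger(__name__)


@dataclass
class LegAnalysis:
    """Everything computed for one leg of one walk."""

    nav: navmod.NAVSeries
    sync_time: float
    offsets: tuple[float, float, float]
    peak_times: np.ndarray
    cycles: list[ev.GaitCycle]
    summary: ev.WalkSummary
    median_shares: dict[str, float]
    spectral_peaks: spec.SpectralPeaks | None


def analyze_series(series: AngularVelocitySeries, corridor_length: float,
                   jerk_threshold: float = 150.0,
                   min_separation: float = 0.5,
                   prominence_frac: float = 0.4,
                   with_spectrum: bool = True) -> LegAnalysis:
    """Run the full single-leg chain on one sensor stream."""
    t0 = detect_sync_start(series, jerk_threshold)
    start = series.timestamps[0]
    win = (max(start, t0 - 4.5), t0 - 0.1)
    offsets = estimate_offsets(series, win)
    dt = series.sample_interval
    walking = series.slice_time(t0 + 3 * dt, series.timestamps[-1])
    nav = navmod.pitch_nav(walking, offsets)
    peaks = ev.detect_midswing_peaks(nav, min_separation, prominence_frac)
    cycles = ev.extract_cycles(nav, peaks)
    summary = ev.summarize_leg(cycles, corridor_length, series.leg)
    seg = ev.walking_segment(peaks, bounds=(nav.timestamps[0],
                                            nav.timestamps[-1]))
    shares = navmod.median_shares(nav, *seg)
    peaks_out = None
    if with_spectrum:
        try:
            freqs, power = spec.power_spectrum(nav, segment=seg)
            peaks_out = spec.dominant_frequencies(freqs, power)
        except Exception as exc:  # noqa: BLE001 - spectral step is optional
            log.warning("spectral step failed for %s leg: %s",
                        series.leg, exc)
    return LegAnalysis(nav=nav, sync_time=t0, offsets=offsets,
                       peak_times=peaks, cycles=cycles, summary=summary,
                       median_shares=shares, spectral_peaks=peaks_out)


def analyze_recording(recording: WalkRecording, **kwargs,
                      ) -> dict[str, LegAnalysis]:
    """Analyze both legs of a recording."""
    return {leg: analyze_series(recording.series(leg),
                                recording.corridor_length, **kwargs)
            for leg in ("left", "right")}


def lesion_leg(recording: WalkRecording) -> str:
    """Leg of interest: the lesion side for patients, left for controls."""
    return recording.lesion_side if recording.lesion_side != "none" \
        else "left"


def cycles_frame(analyses: dict[str, LegAnalysis]) -> pd.DataFrame:
    """One row per valid cycle, both legs."""
    rows = []
    for leg, a in analyses.items():
        for k, c in enumerate(a.cycles):
            rows.append({
                "leg": leg, "cycle": k,
                "t_toeoff": c.events.t_toeoff,
                "t_midswing": c.events.t_midswing,
                "t_heelstrike": c.events.t_heelstrike,
                "t_midstance": c.events.t_midstance,
                **{p: getattr(c, p) for p in ev.PARAMETERS}})
    return pd.DataFrame(rows)


def summary_dict(analyses: dict[str, LegAnalysis]) -> dict:
    """JSON-serializable per-leg summary of one analyzed walk."""
    out = {}
    for leg, a in analyses.items():
        s = a.summary
        entry = {
            "n_strides": s.n_strides,
            "gait_velocity": s.gait_velocity,
            "means": s.means, "sds": s.sds,
            "var_toeoff_time": s.var_toeoff_time,
            "var_heelstrike_time": s.var_heelstrike_time,
            "median_shares": a.median_shares,
            "offsets": list(a.offsets),
            "sync_time": a.sync_time,
        }
        if a.spectral_peaks is not None:
            p = a.spectral_peaks
            entry["spectral"] = {
                "f1": p.f1, "f2": p.f2, "f3": p.f3,
                "amp1": p.amp1, "amp2": p.amp2, "amp3": p.amp3,
                "n_found": p.n_found}
        out[leg] = entry
    return out


# ---------------------------------------------------------------------------
# Cohort-level helpers
# ---------------------------------------------------------------------------

def cohort_configs(n_control: int, n_lvn: int, n_rvn: int, seed: int,
                   **overrides) -> list[SimulationConfig]:
    """Simulation configs for a cohort, one independent seed per subject."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31))
             for c in ss.spawn(n_control + n_lvn + n_rvn)]
    configs = []
    i = 0
    for _ in range(n_control):
        configs.append(SimulationConfig(group="control", seed=seeds[i],
                                        **overrides))
        i += 1
    for side, count in (("left", n_lvn), ("right", n_rvn)):
        for _ in range(count):
            configs.append(SimulationConfig(group="vn", lesion_side=side,
                                            seed=seeds[i], **overrides))
            i += 1
    return configs


def cohort_label(config_or_recording) -> str:
    group = config_or_recording.group
    if group == "control":
        return "normal"
    return "lvn" if config_or_recording.lesion_side == "left" else "rvn"


def analyze_cohort(configs: list[SimulationConfig],
                   subject_variability: bool = True,
                   ) -> list[tuple[str, ev.WalkSummary]]:
    """Simulate and analyze a cohort; one lesion-leg summary per subject.

    With ``subject_variability`` (the default) each subject's cycle
    parameters are drawn around their group's column with the published
    between-subject SDs; otherwise every subject uses the column means.
    """
    from .simulate import (default_params, interpolate_params,
                           sample_subject_params)
    out = []
    for cfg in configs:
        if subject_variability:
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, 99]))
            if cfg.group == "control":
                p = sample_subject_params("normal", rng)
                cfg = dataclasses.replace(cfg, left_params=p,
                                          right_params=p)
            else:
                column = "lvn" if cfg.lesion_side == "left" else "rvn"
                lesion = sample_subject_params(column, rng)
                contra = interpolate_params(
                    lesion, default_params("control", "normal"), 0.5)
                if cfg.lesion_side == "left":
                    cfg = dataclasses.replace(cfg, left_params=lesion,
                                              right_params=contra)
                else:
                    cfg = dataclasses.replace(cfg, left_params=contra,
                                              right_params=lesion)
        rec = simulate_walk(cfg)
        leg = lesion_leg(rec)
        analysis = analyze_series(rec.series(leg), rec.corridor_length,
                                  with_spectrum=False)
        out.append((cohort_label(cfg), analysis.summary))
    return out


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

_RUN_KEYS = {
    "seed", "out_dir", "input_dir", "simulate", "group", "lesion_side",
    "corridor_length", "walking_speed", "stride_time_cv", "amplitude_cv",
    "noise_sd", "roll_yaw_fraction", "stationary_lead",
    "sync_spike_amplitude", "sample_interval", "jerk_threshold",
    "min_separation", "prominence_frac", "cohort", "log_level",
}
_SIM_KEYS = {
    "group", "lesion_side", "corridor_length", "walking_speed",
    "stride_time_cv", "amplitude_cv", "noise_sd", "roll_yaw_fraction",
    "stationary_lead", "sync_spike_amplitude", "sample_interval",
}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "results/run"
    input_dir: str | None = None
    simulate: bool = True
    group: str = "control"
    lesion_side: str = "none"
    corridor_length: float = 88.8
    walking_speed: float | None = None
    stride_time_cv: float = 0.02
    amplitude_cv: float = 0.05
    noise_sd: float = 5.0
    roll_yaw_fraction: float = 0.25
    stationary_lead: float = 5.0
    sync_spike_amplitude: float = 500.0
    sample_interval: float = 0.02
    jerk_threshold: float = 150.0
    min_separation: float = 0.5
    prominence_frac: float = 0.4
    cohort: dict | None = None   # {"n_control": .., "n_lvn": .., "n_rvn": ..}
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        defaults = raw.pop("defaults", {}) or {}
        merged = {**defaults, **raw}
        unknown = set(merged) - _RUN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**merged)

    def simulation_config(self) -> SimulationConfig:
        kwargs = {k: getattr(self, k) for k in _SIM_KEYS}
        return SimulationConfig(seed=self.seed, **kwargs)


def run_full(config: RunConfig) -> Path:
    """Execute the full stage chain and write all artifacts.

    Single-walk mode writes ``cycles.csv``, ``summary.json`` and
    ``peaks.json``; cohort mode additionally writes ``table1.csv`` and
    ``table1.json``.  A run manifest with the resolved configuration and
    stage timings always accompanies the outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": dataclasses.asdict(config), "stages": {}}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s started", name)
                return self

            def __exit__(self, *exc):
                manifest["stages"][name] = round(
                    time.perf_counter() - self.t0, 3)
                log.info("stage %s finished in %.2f s",
                         name, time.perf_counter() - self.t0)
        return _Timer()

    if config.cohort:
        with stage("cohort"):
            cohort = dict(config.cohort)
            configs = cohort_configs(
                int(cohort.get("n_control", 10)),
                int(cohort.get("n_lvn", 5)), int(cohort.get("n_rvn", 5)),
                config.seed,
                **{k: getattr(config, k) for k in _SIM_KEYS
                   if k not in ("group", "lesion_side")})
            summaries = analyze_cohort(configs)
            report = statsmod.build_report(summaries)
            statsmod.report_frame(report).to_csv(out / "table1.csv",
                                                 index=False)
            (out / "table1.json").write_text(
                json.dumps(statsmod.report_json(report), indent=2))
    else:
        with stage("simulate"):
            if config.simulate:
                recording = simulate_walk(config.simulation_config())
                write_recording(recording, out / "recording")
            else:
                if config.input_dir is None:
                    raise ConfigError("simulate=false requires input_dir")
                recording = read_recording(config.input_dir)
        with stage("analyze"):
            analyses = analyze_recording(
                recording, jerk_threshold=config.jerk_threshold,
                min_separation=config.min_separation,
                prominence_frac=config.prominence_frac)
            cycles_frame(analyses).to_csv(out / "cycles.csv", index=False)
            (out / "summary.json").write_text(
                json.dumps(summary_dict(analyses), indent=2))
            skipped = {leg: len(a.peak_times) - 1 - len(a.cycles)
                       for leg, a in analyses.items()}
            manifest["skipped_cycles"] = skipped
        with stage("spectrum"):
            peaks = {leg: summary_dict({leg: a})[leg].get("spectral")
                     for leg, a in analyses.items()}
            (out / "peaks.json").write_text(json.dumps(peaks, indent=2))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
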