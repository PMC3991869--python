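"""Synthetic bilateral shank-gyroscope walk generator.

Emulates the pitch-axis angular-velocity waveform of one gait cycle as seen
by a gyroscope strapped to the mid-shank: a near-zero mid-stance plateau, a
negative trough at toe-off, a large positive peak at mid-swing, a second
negative trough at heel strike, and a smooth return to the plateau.  Presets
are calibrated to the published group means of a continuous 88.8 m corridor
walk study (healthy controls and unilateral vestibular-neuritis patients).

The five published cycle descriptors (both trough/peak amplitudes, both
chord slopes, and the swing time) overdetermine the trough-peak-trough
geometry: with the heel-strike trough pinned above the toe-off trough (the
toe-off trough must remain the global minimum), both chord slopes cannot be
realized together with the published swing time.  The template therefore
honors the amplitudes, the up-slope, and the stride/swing/stance partition
exactly; the descending chord slope is the derived residual and every
template reports its realized value (``CycleTemplate.realized_down_slope``).

Segments between events are raised-cosine arcs: the chord slope between the
toe-off trough and the mid-swing peak equals the configured up-slope
exactly, while the extrema are stationary points of the waveform, so 50 Hz
sampling reads them with second-order (sub-percent) error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .io import AngularVelocitySeries, WalkRecording

#: Published group means of the eight per-cycle gait parameters
#: (columns: healthy controls, left-lesion VN, right-lesion VN).
TABLE_MEANS = {
    "normal": {
        "max_nav": 368.6, "min_nav": -172.3,
        "down_slope": -3003.0, "up_slope": 2968.7,
        "stride_time": 0.98, "swing_time": 0.389, "stance_time": 0.591,
        "stance_ratio": 60.4,
    },
    "lvn": {
        "max_nav": 258.6, "min_nav": -125.8,
        "down_slope": -2139.4, "up_slope": 1692.6,
        "stride_time": 1.15, "swing_time": 0.430, "stance_time": 0.722,
        "stance_ratio": 62.7,
    },
    "rvn": {
        "max_nav": 349.6, "min_nav": -195.0,
        "down_slope": -3251.9, "up_slope": 1893.1,
        "stride_time": 1.12, "swing_time": 0.485, "stance_time": 0.633,
        "stance_ratio": 56.6,
    },
}

#: Published between-subject standard deviations for the same parameters.
TABLE_SDS = {
    "normal": {
        "max_nav": 42.5, "min_nav": 34.5,
        "down_slope": 341.7, "up_slope": 973.9,
        "stride_time": 0.062, "swing_time": 0.060, "stance_time": 0.044,
    },
    "lvn": {
        "max_nav": 42.3, "min_nav": 26.9,
        "down_slope": 401.1, "up_slope": 429.0,
        "stride_time": 0.115, "swing_time": 0.053, "stance_time": 0.083,
    },
    "rvn": {
        "max_nav": 51.1, "min_nav": 47.9,
        "down_slope": 1021.3, "up_slope": 144.5,
        "stride_time": 0.069, "swing_time": 0.046, "stance_time": 0.059,
    },
}

#: Group-mean over-ground walking speeds, m/s.
DEFAULT_WALKING_SPEED = {"control": 1.11, "vn": 0.84}

#: Heel-strike trough depth relative to the toe-off trough (free parameter;
#: < 1 keeps the toe-off trough the global minimum of the cycle).
HEELSTRIKE_FRACTION = 0.85


def timing_identity_residuals(stride_time: float, swing_time: float,
                              stance_time: float, stance_ratio_pct: float,
                              ) -> tuple[float, float]:
    """Residuals of the two definitional timing identities.

    Returns ``(stride − swing − stance, ratio − 100·stance/stride)`` so a
    consistent parameter row yields (0, 0).  Used to check that a published
    or computed summary row is arithmetically self-consistent.
    """
    return (stride_time - swing_time - stance_time,
            stance_ratio_pct - 100.0 * stance_time / stride_time)


@dataclass(frozen=True)
class CycleParams:
    """Template parameters of one gait cycle on the pitch channel.

    Angular velocities are in deg/s, times in seconds, slopes in deg/s^2.
    ``a_toeoff`` and ``a_heelstrike`` are the (negative) trough values,
    ``a_midswing`` the (positive) peak.
    """

    stride_time: float
    swing_time: float
    stance_time: float
    a_toeoff: float
    a_midswing: float
    a_heelstrike: float
    up_slope: float
    down_slope: float

    def validate(self) -> None:
        if self.stride_time <= 0:
            raise ParameterError("stride_time must be positive")
        if abs(self.stride_time - self.swing_time - self.stance_time) > 1e-9:
            raise ParameterError(
                "stride_time must equal swing_time + stance_time "
                f"(got {self.stride_time} vs "
                f"{self.swing_time + self.stance_time})")
        if not (self.a_toeoff < self.a_heelstrike < 0.0 < self.a_midswing):
            raise ParameterError(
                "amplitude ordering a_toeoff < a_heelstrike < 0 < a_midswing "
                "violated (the toe-off trough must be the global minimum)")
        if not (self.up_slope > 0.0 > self.down_slope):
            raise ParameterError("require up_slope > 0 > down_slope")
        d_up = (self.a_midswing - self.a_toeoff) / self.up_slope
        d_dn = (self.a_heelstrike - self.a_midswing) / self.down_slope
        if not 0.0 < d_up < self.swing_time:
            raise ParameterError(
                f"rise duration (a_midswing − a_toeoff)/up_slope = {d_up:.3f}"
                f" s must be shorter than swing_time {self.swing_time:.3f} s")
        if not 0.0 < d_dn < self.swing_time:
            raise ParameterError(
                f"fall duration (a_heelstrike − a_midswing)/down_slope = "
                f"{d_dn:.3f} s must be shorter than swing_time")

    def scaled(self, duration: float = 1.0, amplitude: float = 1.0,
               ) -> "CycleParams":
        """Jointly rescale durations and amplitudes (invariant-preserving)."""
        return CycleParams(
            stride_time=self.stride_time * duration,
            swing_time=self.swing_time * duration,
            stance_time=self.stance_time * duration,
            a_toeoff=self.a_toeoff * amplitude,
            a_midswing=self.a_midswing * amplitude,
            a_heelstrike=self.a_heelstrike * amplitude,
            up_slope=self.up_slope * amplitude / duration,
            down_slope=self.down_slope * amplitude / duration,
        )


def default_params(group: str, column: str) -> CycleParams:
    """Preset cycle parameters from the published group-mean columns.

    ``group`` is ``control`` or ``vn``; ``column`` is ``normal``, ``lvn`` or
    ``rvn`` and must match the group.  The published stride and stance times
    are preserved verbatim; swing is recomputed as stride − stance so the
    timing identity holds exactly (the published swing differs by ≤ 0.002 s
    due to rounding).  The heel-strike trough is 0.85 × the toe-off trough.
    """
    if group not in ("control", "vn"):
        raise ParameterError(f"unknown group {group!r}")
    if column not in TABLE_MEANS:
        raise ParameterError(f"unknown preset column {column!r}")
    if (group == "control") != (column == "normal"):
        raise ParameterError(f"column {column!r} is not a {group!r} preset")
    row = TABLE_MEANS[column]
    stride, stance = row["stride_time"], row["stance_time"]
    return CycleParams(
        stride_time=stride,
        swing_time=stride - stance,
        stance_time=stance,
        a_toeoff=row["min_nav"],
        a_midswing=row["max_nav"],
        a_heelstrike=HEELSTRIKE_FRACTION * row["min_nav"],
        up_slope=row["up_slope"],
        down_slope=row["down_slope"],
    )


def interpolate_params(p: CycleParams, q: CycleParams, weight: float,
                       ) -> CycleParams:
    """Field-wise blend ``weight·p + (1−weight)·q`` (stance closes stride)."""
    def mix(a: float, b: float) -> float:
        return weight * a + (1.0 - weight) * b

    stride = mix(p.stride_time, q.stride_time)
    stance = mix(p.stance_time, q.stance_time)
    out = CycleParams(
        stride_time=stride,
        swing_time=stride - stance,
        stance_time=stance,
        a_toeoff=mix(p.a_toeoff, q.a_toeoff),
        a_midswing=mix(p.a_midswing, q.a_midswing),
        a_heelstrike=mix(p.a_heelstrike, q.a_heelstrike),
        up_slope=mix(p.up_slope, q.up_slope),
        down_slope=mix(p.down_slope, q.down_slope),
    )
    out.validate()
    return out


def sample_subject_params(column: str, rng: np.random.Generator,
                          ) -> CycleParams:
    """Draw one subject's cycle parameters around a preset column.

    Parameters are drawn independently from normals with the published
    between-subject SDs, then reconciled: stance is kept inside a
    physiological fraction of stride, swing closes the timing identity, and
    the slopes are floored so both rise and fall fit inside the swing phase.
    """
    m, s = TABLE_MEANS[column], TABLE_SDS[column]
    for _ in range(100):
        stride = rng.normal(m["stride_time"], s["stride_time"])
        stance = rng.normal(m["stance_time"], s["stance_time"])
        a_ms = rng.normal(m["max_nav"], s["max_nav"])
        a_to = rng.normal(m["min_nav"], s["min_nav"])
        up = rng.normal(m["up_slope"], s["up_slope"])
        down = rng.normal(m["down_slope"], s["down_slope"])
        if stride < 0.6 or a_ms < 50.0 or a_to > -30.0:
            continue
        stance = float(np.clip(stance, 0.45 * stride, 0.75 * stride))
        swing = stride - stance
        a_hs = HEELSTRIKE_FRACTION * a_to
        up = max(up, (a_ms - a_to) / (0.85 * swing))
        down = min(down, (a_hs - a_ms) / (0.85 * swing))
        try:
            params = CycleParams(stride, swing, stance, a_to, a_ms, a_hs,
                                 up, down)
            params.validate()
            return params
        except ParameterError:
            continue
    raise ParameterError(f"could not draw valid parameters for {column!r}")


@dataclass
class CycleTemplate:
    """One stride's noise-free pitch waveform with its event schedule.

    Event times are in stride-local seconds; ``waveform`` is the template
    sampled on the acquisition grid (``round(stride_time/sample_interval)``
    samples).  ``realized_down_slope`` is the chord slope actually produced
    between the mid-swing peak and the heel-strike trough.
    """

    params: CycleParams
    sample_interval: float
    t_toeoff: float
    t_midswing: float
    t_heelstrike: float
    t_midstance: float
    d_pre: float
    d_post: float
    realized_down_slope: float
    waveform: np.ndarray = field(repr=False)

    @property
    def realized_params(self) -> CycleParams:
        """Cycle parameters as the waveform actually realizes them."""
        return replace(self.params, down_slope=self.realized_down_slope)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the continuous template at stride-local times ``t``."""
        p = self.params
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        if p.a_midswing == p.a_toeoff == p.a_heelstrike == 0.0:
            return out

        t_e, t_f, t_g = self.t_toeoff, self.t_midswing, self.t_heelstrike
        p1 = t_e - self.d_pre

        def arc(x, dur, v0, v1):
            return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * x / dur))

        m = (t >= p1) & (t < t_e)
        out[m] = arc(t[m] - p1, self.d_pre, 0.0, p.a_toeoff)
        m = (t >= t_e) & (t < t_f)
        out[m] = arc(t[m] - t_e, t_f - t_e, p.a_toeoff, p.a_midswing)
        m = (t >= t_f) & (t < t_g)
        out[m] = arc(t[m] - t_f, t_g - t_f, p.a_midswing, p.a_heelstrike)
        m = (t >= t_g) & (t < t_g + self.d_post)
        out[m] = arc(t[m] - t_g, self.d_post, p.a_heelstrike, 0.0)
        return out


def make_cycle_template(params: CycleParams, sample_interval: float = 0.02,
                        validate: bool = True) -> CycleTemplate:
    """Build the continuous one-stride template and its sampled waveform.

    The toe-off trough is snapped to the sampling grid (relative to the
    cycle start) so a zero-jitter simulation reads the trough value exactly.
    """
    if sample_interval <= 0:
        raise ParameterError("sample_interval must be positive")
    if validate:
        params.validate()

    T = params.stride_time
    n = int(round(T / sample_interval))

    if params.a_midswing == params.a_toeoff == params.a_heelstrike == 0.0:
        # Degenerate flat template: keep a nominal event schedule.
        tmpl = CycleTemplate(params, sample_interval,
                             t_toeoff=params.stance_time,
                             t_midswing=params.stance_time
                             + 0.5 * params.swing_time,
                             t_heelstrike=params.stance_time
                             + params.swing_time,
                             t_midstance=0.5 * params.stance_time,
                             d_pre=0.0, d_post=0.0,
                             realized_down_slope=0.0,
                             waveform=np.zeros(n))
        return tmpl

    stance, swing = params.stance_time, params.swing_time
    d_up = (params.a_midswing - params.a_toeoff) / params.up_slope
    d_fall = swing - d_up
    d_pre = min(0.12, 0.4 * stance)
    d_post = min(0.12, 0.4 * stance)

    t_e_raw = d_pre + 0.5 * (stance - d_pre - d_post)
    t_e = round(t_e_raw / sample_interval) * sample_interval
    t_e = float(np.clip(t_e, d_pre, stance - d_post))
    t_f = t_e + d_up
    t_g = t_e + swing
    t_h = t_g + d_post + 0.5 * (T - t_g - d_post)
    realized_down = (params.a_heelstrike - params.a_midswing) / d_fall

    tmpl = CycleTemplate(params, sample_interval, t_e, t_f, t_g, min(t_h, T),
                         d_pre, d_post, realized_down, waveform=np.zeros(0))
    tmpl.waveform = tmpl.evaluate(np.arange(n) * sample_interval)
    return tmpl


@dataclass
class SimulationConfig:
    """Generator configuration for one simulated corridor walk.

    Defaults are the study conditions: 50 Hz sampling, an 88.8 m corridor,
    a deliberate two-sample synchronization shake at the start, 5 s of
    stationary standing before and after the walk, small constant per-axis
    gyro biases, mild stride-to-stride variability and broadband sensor
    noise.  ``walking_speed=None`` resolves to the group mean (1.11 m/s
    control, 0.84 m/s vestibular neuritis).
    """

    group: str = "control"
    lesion_side: str = "none"
    left_params: CycleParams | None = None
    right_params: CycleParams | None = None
    stride_time_cv: float = 0.02
    amplitude_cv: float = 0.05
    noise_sd: float = 5.0
    roll_yaw_fraction: float = 0.25
    corridor_length: float = 88.8
    walking_speed: float | None = None
    stationary_lead: float = 5.0
    sync_spike_amplitude: float = 500.0
    sample_interval: float = 0.02
    lead_offsets: tuple[float, float, float] = (2.0, -3.0, 1.5)
    seed: int = 0

    def validate(self) -> None:
        if self.group not in ("control", "vn"):
            raise ParameterError(f"unknown group {self.group!r}")
        if self.lesion_side not in ("left", "right", "none"):
            raise ParameterError(f"unknown lesion_side {self.lesion_side!r}")
        if self.group == "vn" and self.lesion_side == "none":
            raise ParameterError("group 'vn' requires lesion_side "
                                 "'left' or 'right'")
        if self.group == "control" and self.lesion_side != "none":
            raise ParameterError("control group must have lesion_side 'none'")
        for name in ("stride_time_cv", "amplitude_cv"):
            v = getattr(self, name)
            if not 0.0 <= v < 0.5:
                raise ParameterError(f"{name} must lie in [0, 0.5)")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if self.corridor_length <= 0:
            raise ParameterError("corridor_length must be positive")
        if self.walking_speed is not None and self.walking_speed <= 0:
            raise ParameterError("walking_speed must be positive")
        if self.sample_interval <= 0:
            raise ParameterError("sample_interval must be positive")
        if self.stationary_lead < 1.0:
            raise ParameterError("stationary_lead must be at least 1 s")

    def resolved_speed(self) -> float:
        if self.walking_speed is not None:
            return self.walking_speed
        return DEFAULT_WALKING_SPEED[self.group]


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int,
                       ) -> np.ndarray:
    """Unit-mean multiplicative log-normal jitter with the given CV."""
    if cv == 0.0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=math.sqrt(sigma2), size=n)


def simulate_leg(params: CycleParams, n_strides: int,
                 config: SimulationConfig, phase_offset: float = 0.0,
                 rng: np.random.Generator | None = None, leg: str = "left",
                 return_truth: bool = False):
    """Simulate one shank sensor's full recording.

    Layout on the time axis: ``stationary_lead`` seconds of biased, noisy
    standing; a two-sample synchronization spike on all axes; the walking
    segment (``n_strides`` jittered cycle templates, the right leg delayed
    by ``phase_offset``); and a stationary tail.  Roll (x) and yaw-ish (y)
    channels are independently amplitude-jittered scaled copies of the pitch
    waveform.  With ``return_truth=True`` also returns the per-cycle
    analytic event times used by oracle tests.
    """
    if n_strides < 1:
        raise ParameterError("n_strides must be at least 1")
    config.validate()
    params.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    dt = config.sample_interval
    n_lead = int(round(config.stationary_lead / dt))
    dur_f = _lognormal_factors(rng, config.stride_time_cv, n_strides)
    amp_f = _lognormal_factors(rng, config.amplitude_cv, n_strides)
    x_f = _lognormal_factors(rng, config.amplitude_cv, n_strides)
    y_f = _lognormal_factors(rng, config.amplitude_cv, n_strides)

    templates = [make_cycle_template(params.scaled(d, a), dt)
                 for d, a in zip(dur_f, amp_f)]
    t_walk0 = (n_lead + 2) * dt + phase_offset
    starts = t_walk0 + np.concatenate(
        [[0.0], np.cumsum([t.params.stride_time for t in templates])])
    t_end = starts[-1]

    n_total = int(math.floor(t_end / dt)) + 1 + n_lead
    t = np.arange(n_total) * dt
    gz = np.zeros(n_total)
    gx = np.zeros(n_total)
    gy = np.zeros(n_total)

    for k, tmpl in enumerate(templates):
        i0 = int(math.ceil(starts[k] / dt - 1e-9))
        i1 = int(math.ceil(starts[k + 1] / dt - 1e-9))
        local = t[i0:i1] - starts[k]
        vals = tmpl.evaluate(local)
        gz[i0:i1] = vals
        gx[i0:i1] = config.roll_yaw_fraction * x_f[k] * vals
        gy[i0:i1] = config.roll_yaw_fraction * y_f[k] * vals

    ox, oy, oz = config.lead_offsets
    gx += ox
    gy += oy
    gz += oz
    if config.noise_sd > 0:
        gx += rng.normal(0.0, config.noise_sd, n_total)
        gy += rng.normal(0.0, config.noise_sd, n_total)
        gz += rng.normal(0.0, config.noise_sd, n_total)
    # Synchronization shake: a deliberate two-sample burst on every axis.
    for ch in (gx, gy, gz):
        ch[n_lead:n_lead + 2] += config.sync_spike_amplitude

    series = AngularVelocitySeries(timestamps=t, gx=gx, gy=gy, gz=gz,
                                   leg=leg, sensor_id=f"sim-{leg}")
    if not return_truth:
        return series
    truth = {
        "walking_start": t_walk0,
        "cycle_starts": starts[:-1],
        "toeoff_times": starts[:-1] + np.array(
            [tm.t_toeoff for tm in templates]),
        "midswing_times": starts[:-1] + np.array(
            [tm.t_midswing for tm in templates]),
        "heelstrike_times": starts[:-1] + np.array(
            [tm.t_heelstrike for tm in templates]),
        "templates": templates,
        "sync_time": n_lead * dt,
    }
    return series, truth


def resolve_leg_params(config: SimulationConfig,
                       ) -> tuple[CycleParams, CycleParams]:
    """Left/right cycle parameters implied by the group preset.

    For a VN walk the lesion-side leg uses the matching published column and
    the contralateral leg a 50 % blend toward the control preset (the study
    reports asymmetry but prints no contralateral column).
    """
    if config.left_params is not None and config.right_params is not None:
        return config.left_params, config.right_params
    if config.group == "control":
        p = default_params("control", "normal")
        return (config.left_params or p, config.right_params or p)
    column = "lvn" if config.lesion_side == "left" else "rvn"
    lesion = default_params("vn", column)
    contra = interpolate_params(lesion, default_params("control", "normal"),
                                0.5)
    if config.lesion_side == "left":
        return (config.left_params or lesion, config.right_params or contra)
    return (config.left_params or contra, config.right_params or lesion)


def simulate_walk(config: SimulationConfig) -> WalkRecording:
    """Simulate both legs of one corridor walk.

    The right leg is phase-delayed by half a stride (the two legs move in
    reciprocally opposite phase).  The stride count per leg covers the
    corridor at the resolved walking speed:
    ``ceil(corridor_length / (speed × stride_time))``.
    """
    config.validate()
    left_params, right_params = resolve_leg_params(config)
    speed = config.resolved_speed()
    ss = np.random.SeedSequence(config.seed)
    rng_l, rng_r = (np.random.default_rng(c) for c in ss.spawn(2))

    def n_strides(p: CycleParams) -> int:
        return int(math.ceil(config.corridor_length
                             / (speed * p.stride_time)))

    left = simulate_leg(left_params, n_strides(left_params), config,
                        phase_offset=0.0, rng=rng_l, leg="left")
    right = simulate_leg(right_params, n_strides(right_params), config,
                         phase_offset=0.5 * right_params.stride_time,
                         rng=rng_r, leg="right")
    return WalkRecording(left=left, right=right, group=config.group,
                         lesion_side=config.lesion_side,
                         corridor_length=config.corridor_length,
                         subject_meta={})
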