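"""Gait-event detection and per-cycle parameters on the pitch signal.

Each gait cycle of the shank pitch signal carries four canonical events:
the toe-off trough (the global minimum of the cycle), the mid-swing peak
(the global maximum), the heel-strike trough (the first local minimum after
the peak), and mid-stance (where the signal sits closest to zero).  Strides
are delimited toe-off to toe-off, so stride = swing + stance holds
identically with stance defined heel-strike to next toe-off.  Event times
carry the resolution of the 50 Hz sampling grid (one sample, 20 ms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import MalformedCycleError, TooFewStridesError
from .io import WalkRecording
from .nav import NAVSeries

log = logging.getLogger(__name__)

#: The per-cycle parameters summarized at walk level.
PARAMETERS = ("max_nav", "min_nav", "up_slope", "down_slope",
              "stride_time", "swing_time", "stance_time", "stance_ratio")


@dataclass
class GaitEvents:
    """The four events of one gait cycle: times (s) and pitch values (deg/s)."""

    t_toeoff: float
    t_midswing: float
    t_heelstrike: float
    t_midstance: float
    v_toeoff: float
    v_midswing: float
    v_heelstrike: float
    v_midstance: float

    def validate(self) -> None:
        if not (self.t_toeoff < self.t_midswing < self.t_heelstrike
                < self.t_midstance):
            raise MalformedCycleError("event times out of order")
        if not (self.v_toeoff <= self.v_heelstrike < self.v_midswing):
            raise MalformedCycleError(
                "toe-off trough is not the deepest event of the cycle")


@dataclass
class GaitCycle:
    """One stride's events and derived parameters."""

    events: GaitEvents
    peak_time: float            # mid-swing peak, reference for timing jitter
    t_next_heelstrike: float    # following cycle's heel strike (walk span)
    stride_time: float
    swing_time: float
    stance_time: float
    stance_ratio: float         # percent
    max_nav: float
    min_nav: float
    up_slope: float
    down_slope: float


@dataclass
class WalkSummary:
    """Per-leg aggregates over all valid cycles of one walk."""

    leg: str
    n_strides: int
    gait_velocity: float                  # m/s
    means: dict[str, float]
    sds: dict[str, float]
    var_toeoff_time: float                # s^2, peak-relative
    var_heelstrike_time: float            # s^2, peak-relative


def detect_midswing_peaks(nav: NAVSeries, min_separation: float = 0.5,
                          prominence_frac: float = 0.4) -> np.ndarray:
    """Times of the mid-swing peaks (the per-cycle maxima).

    Local maxima of the pitch signal with height and prominence at least
    ``prominence_frac`` times the 90th percentile of the positive samples,
    separated by at least ``min_separation`` seconds.  The height floor
    rejects the near-zero mid-stance plateau, which lies between two
    negative troughs and therefore carries large prominence of its own.
    """
    pitch = nav.pitch
    positive = pitch[pitch > 0]
    if positive.size == 0:
        raise TooFewStridesError("signal has no positive excursion")
    threshold = max(prominence_frac * float(np.percentile(positive, 90)),
                    1e-9)
    distance = max(1, int(round(min_separation / nav.sample_interval)))
    idx, _ = find_peaks(pitch, height=threshold, prominence=threshold,
                        distance=distance)
    if idx.size < 3:
        raise TooFewStridesError(
            f"only {idx.size} mid-swing peaks found; need at least 3")
    return nav.timestamps[idx]


def _index_range(nav: NAVSeries, t0: float, t1: float) -> tuple[int, int]:
    """Half-open index window for times in (t0, t1)."""
    i0 = int(np.searchsorted(nav.timestamps, t0, side="right"))
    i1 = int(np.searchsorted(nav.timestamps, t1, side="left"))
    return i0, i1


def _first_local_min(pitch: np.ndarray, i0: int, i1: int) -> int:
    """Index of the first convincing local minimum in [i0, i1).

    Noise can dimple the steep descent from the peak, so candidate minima
    shallower than half the deepest value in the window are ignored.
    """
    if i1 - i0 < 3:
        raise MalformedCycleError("window too short for a local minimum")
    seg = pitch[i0:i1]
    floor = float(seg.min())
    if floor >= 0:
        raise MalformedCycleError("no negative trough after the peak")
    for j in range(1, len(seg) - 1):
        if (seg[j] < seg[j - 1] and seg[j] <= seg[j + 1]
                and seg[j] <= 0.5 * floor):
            return i0 + j
    raise MalformedCycleError("no local minimum after the mid-swing peak")


def detect_cycle_events(nav: NAVSeries, peak_time: float,
                        prev_peak_time: float, next_peak_time: float,
                        ) -> GaitEvents:
    """Locate the four events of the cycle around one mid-swing peak.

    Toe-off is the minimum between the midpoint to the previous peak and the
    peak (the midpoint start avoids capturing the previous cycle's
    heel-strike trough); heel strike is the first local minimum after the
    peak; mid-stance is where |pitch| is smallest between heel strike and
    the next cycle's toe-off.
    """
    t = nav.timestamps
    pitch = nav.pitch

    i0, i1 = _index_range(nav, 0.5 * (prev_peak_time + peak_time), peak_time)
    if i1 - i0 < 1:
        raise MalformedCycleError("empty toe-off search window")
    i_to = i0 + int(np.argmin(pitch[i0:i1]))

    i_peak = int(np.argmin(np.abs(t - peak_time)))

    j0, j1 = _index_range(nav, peak_time, 0.5 * (peak_time + next_peak_time))
    i_hs = _first_local_min(pitch, max(j0, i_peak + 1), j1)

    # Next cycle's toe-off bounds the mid-stance search.
    k0, k1 = _index_range(nav, 0.5 * (peak_time + next_peak_time),
                          next_peak_time)
    if k1 - k0 < 1:
        raise MalformedCycleError("empty next-toe-off search window")
    i_next_to = k0 + int(np.argmin(pitch[k0:k1]))
    if i_next_to - i_hs < 2:
        raise MalformedCycleError("no room for a mid-stance sample")
    i_ms = i_hs + 1 + int(np.argmin(np.abs(pitch[i_hs + 1:i_next_to])))

    ev = GaitEvents(
        t_toeoff=float(t[i_to]), t_midswing=float(t[i_peak]),
        t_heelstrike=float(t[i_hs]), t_midstance=float(t[i_ms]),
        v_toeoff=float(pitch[i_to]), v_midswing=float(pitch[i_peak]),
        v_heelstrike=float(pitch[i_hs]), v_midstance=float(pitch[i_ms]))
    ev.validate()
    # The toe-off trough must be the deepest point of the cycle's active
    # span (through mid-stance).  The next cycle's toe-off region is left
    # out: under noise its trough realization is deeper half the time.
    if float(pitch[i_to:i_ms + 1].min()) < ev.v_toeoff - 1e-9:
        raise MalformedCycleError(
            "a deeper trough than toe-off exists within the stride")
    return ev


def compute_cycle(events: GaitEvents, events_next: GaitEvents) -> GaitCycle:
    """Derive one stride's parameters from two consecutive event sets.

    Stride runs toe-off to next toe-off; stance runs heel strike to next
    toe-off; swing closes the identity.  Slopes are event-to-event chords.
    """
    stride = events_next.t_toeoff - events.t_toeoff
    stance = events_next.t_toeoff - events.t_heelstrike
    swing = stride - stance
    if stride <= 0 or stance <= 0 or swing <= 0:
        raise MalformedCycleError("non-positive stride/stance/swing duration")
    up = ((events.v_midswing - events.v_toeoff)
          / (events.t_midswing - events.t_toeoff))
    down = ((events.v_heelstrike - events.v_midswing)
            / (events.t_heelstrike - events.t_midswing))
    if not (up > 0 > down):
        raise MalformedCycleError("cycle slopes have the wrong sign")
    return GaitCycle(events=events, peak_time=events.t_midswing,
                     t_next_heelstrike=events_next.t_heelstrike,
                     stride_time=stride, swing_time=swing,
                     stance_time=stance,
                     stance_ratio=100.0 * stance / stride,
                     max_nav=events.v_midswing, min_nav=events.v_toeoff,
                     up_slope=up, down_slope=down)


def _events_for_peaks(nav: NAVSeries, peak_times: np.ndarray,
                      ) -> list[GaitEvents | None]:
    """Events per detected peak; ``None`` where a cycle is malformed."""
    peaks = np.asarray(peak_times, dtype=float)
    gap = float(np.median(np.diff(peaks)))
    prevs = np.concatenate([[peaks[0] - gap], peaks[:-1]])
    nexts = np.concatenate([peaks[1:], [peaks[-1] + gap]])
    events: list[GaitEvents | None] = []
    for peak, prev, nxt in zip(peaks, prevs, nexts):
        try:
            events.append(detect_cycle_events(nav, peak, prev, nxt))
        except MalformedCycleError as exc:
            log.info("skipping cycle at %.2f s: %s", peak, exc)
            events.append(None)
    return events


def extract_cycles(nav: NAVSeries, peak_times: np.ndarray,
                   ) -> list[GaitCycle]:
    """All valid strides of a walking segment, skipping malformed cycles."""
    events = _events_for_peaks(nav, peak_times)
    cycles = []
    for ev, ev_next in zip(events[:-1], events[1:]):
        if ev is None or ev_next is None:
            continue
        try:
            cycles.append(compute_cycle(ev, ev_next))
        except MalformedCycleError as exc:
            log.info("skipping cycle at %.2f s: %s", ev.t_midswing, exc)
    return cycles


def cycle_ensemble(nav: NAVSeries, peak_times: np.ndarray,
                   n_points: int = 101,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ensemble mean and SD over the time-normalized stride.

    Each toe-off-to-toe-off cycle is linearly resampled to ``n_points``
    points of normalized stride time in [0, 1]; returns (grid, mean, SD).
    """
    events = [ev for ev in _events_for_peaks(nav, peak_times)
              if ev is not None]
    if len(events) < 4:
        raise TooFewStridesError("need at least 3 complete cycles")
    toeoffs = np.array([ev.t_toeoff for ev in events])
    grid = np.linspace(0.0, 1.0, n_points)
    rows = []
    for t0, t1 in zip(toeoffs[:-1], toeoffs[1:]):
        rows.append(np.interp(t0 + grid * (t1 - t0), nav.timestamps,
                              nav.pitch))
    stack = np.vstack(rows)
    return grid, stack.mean(axis=0), stack.std(axis=0)


def walking_segment(peak_times: np.ndarray,
                    bounds: tuple[float, float] | None = None,
                    ) -> tuple[float, float]:
    """Walking-segment bounds: first to last peak, padded one mean stride."""
    peaks = np.asarray(peak_times, dtype=float)
    pad = float(np.mean(np.diff(peaks)))
    lo, hi = peaks[0] - pad, peaks[-1] + pad
    if bounds is not None:
        lo, hi = max(lo, bounds[0]), min(hi, bounds[1])
    return lo, hi


def summarize_leg(cycles: list[GaitCycle], corridor_length: float,
                  leg: str) -> WalkSummary:
    """Aggregate one leg's cycles into a walk summary.

    Gait velocity is the corridor length divided by the first-toe-off to
    last-heel-strike duration.  Event-timing variances are computed on
    peak-relative event times (each event referenced to its own cycle's
    mid-swing peak), which removes the cumulative drift of the stride clock.
    """
    if len(cycles) < 3:
        raise TooFewStridesError(
            f"need at least 3 valid cycles, got {len(cycles)}")
    means = {p: float(np.mean([getattr(c, p) for c in cycles]))
             for p in PARAMETERS}
    sds = {p: float(np.std([getattr(c, p) for c in cycles], ddof=1))
           for p in PARAMETERS}
    first_to = cycles[0].events.t_toeoff
    last_hs = max(cycles[-1].events.t_heelstrike,
                  cycles[-1].t_next_heelstrike)
    duration = last_hs - first_to
    to_rel = [c.events.t_toeoff - c.peak_time for c in cycles]
    hs_rel = [c.events.t_heelstrike - c.peak_time for c in cycles]
    return WalkSummary(
        leg=leg, n_strides=len(cycles),
        gait_velocity=float(corridor_length / duration),
        means=means, sds=sds,
        var_toeoff_time=float(np.var(to_rel, ddof=1)),
        var_heelstrike_time=float(np.var(hs_rel, ddof=1)))


def summarize_walk(recording: WalkRecording, cycles_left: list[GaitCycle],
                   cycles_right: list[GaitCycle],
                   ) -> tuple[WalkSummary, WalkSummary]:
    """Per-leg walk summaries for an analyzed recording."""
    return (summarize_leg(cycles_left, recording.corridor_length, "left"),
            summarize_leg(cycles_right, recording.corridor_length, "right"))
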