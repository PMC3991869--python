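"""Normalized angular velocity (NAV).

Two distinct quantities travel under the NAV name and this module computes
both.  (1) Per-axis *share ratios*: at every sample, each axis's fraction of
the total angular-velocity magnitude, computed on absolute deviations from
the stationary zero so the shares are bounded in [0, 1] and sum to one;
they quantify how much of the shank's rotation is pitch versus roll/yaw.
(2) The *offset-corrected pitch signal* (gz minus its stationary zero, in
deg/s), which carries the gait-cycle waveform that all per-cycle parameters
are read from.  Shares are undefined (NaN) where the total deviation falls
below 1 deg/s — the segment is effectively stationary there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AngularVelocitySeries

SHARE_EPSILON = 1.0  # deg/s; below this total motion, shares are undefined


@dataclass
class NAVSeries:
    """Offset-corrected pitch signal plus per-sample axis shares."""

    timestamps: np.ndarray
    pitch: np.ndarray
    share_x: np.ndarray
    share_y: np.ndarray
    share_z: np.ndarray
    leg: str

    @property
    def sample_interval(self) -> float:
        return float(np.median(np.diff(self.timestamps)))

    def slice_time(self, t0: float, t1: float) -> "NAVSeries":
        m = (self.timestamps >= t0 - 1e-9) & (self.timestamps <= t1 + 1e-9)
        return NAVSeries(self.timestamps[m], self.pitch[m], self.share_x[m],
                         self.share_y[m], self.share_z[m], self.leg)


def axis_share(series: AngularVelocitySeries,
               offsets: tuple[float, float, float],
               epsilon: float = SHARE_EPSILON,
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample share of each axis in the total angular-velocity magnitude.

    share_a = |g_a − o_a| / Σ_axes |g_axis − o_axis|; samples whose
    denominator is below ``epsilon`` are NaN.  Shares are scale-invariant
    and, where defined, sum to one exactly.
    """
    devs = [np.abs(ch - off) for ch, off in
            zip((series.gx, series.gy, series.gz), offsets)]
    denom = devs[0] + devs[1] + devs[2]
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = [np.where(denom >= epsilon, d / denom, np.nan)
                  for d in devs]
    return shares[0], shares[1], shares[2]


def pitch_nav(series: AngularVelocitySeries,
              offsets: tuple[float, float, float],
              reference_leg: str = "left") -> NAVSeries:
    """Offset-corrected pitch angular velocity with axis shares attached.

    All sensors share one physical orientation, so no sign flip is applied
    between legs; ``reference_leg`` only records which leg downstream
    presentation treats as the reference.
    """
    sx, sy, sz = axis_share(series, offsets)
    return NAVSeries(timestamps=series.timestamps,
                     pitch=series.gz - offsets[2],
                     share_x=sx, share_y=sy, share_z=sz, leg=series.leg)


def median_shares(nav: NAVSeries, t0: float | None = None,
                  t1: float | None = None) -> dict[str, float]:
    """Per-axis median share over a segment (the walk-level axial summary)."""
    sub = nav
    if t0 is not None or t1 is not None:
        sub = nav.slice_time(t0 if t0 is not None else nav.timestamps[0],
                             t1 if t1 is not None else nav.timestamps[-1])
    return {axis: float(np.nanmedian(getattr(sub, f"share_{axis}")))
            for axis in ("x", "y", "z")}
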