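"""Dominant gait frequencies from the pitch-signal power spectrum.

Walking is periodic at the stride rate, so the pitch signal's spectrum
shows a fundamental peak (f1, the cadence of one leg, ~1 Hz) and harmonics
(f2 ≈ 2·f1, f3 ≈ 3·f1).  A single full-segment periodogram is used rather
than averaged short windows: corridor walks last 60–110 s, the quantity of
interest is peak location, and the full segment gives the finest frequency
grid (1/duration).  The analysis band is 0.3–6 Hz — below 0.3 Hz is drift,
above 6 Hz is noise for normal walking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.signal.windows import hann

from .errors import SegmentTooShortError
from .nav import NAVSeries

BAND = (0.3, 6.0)  # Hz
MIN_DURATION = 10.0  # s; gives frequency resolution <= 0.1 Hz


@dataclass
class SpectralPeaks:
    """The three dominant frequencies, ordered f1 < f2 < f3.

    Missing peaks (e.g. in noise-only signals) are NaN; ``n_found`` counts
    the qualifying maxima.  Amplitudes are band-normalized power.
    """

    f1: float
    f2: float
    f3: float
    amp1: float
    amp2: float
    amp3: float
    n_found: int


def power_spectrum(nav: NAVSeries,
                   segment: tuple[float, float] | None = None,
                   normalize: bool = True,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed periodogram of the pitch signal over a segment.

    The segment must last at least 10 s (frequency resolution ≤ 0.1 Hz).
    The one-sided power satisfies Parseval's identity,
    ``sum(power) = n · sum((w·x)^2)``; with ``normalize=True`` it is
    rescaled to sum to one over the 0.3–6 Hz analysis band.
    """
    sub = nav if segment is None else nav.slice_time(*segment)
    x = sub.pitch
    dt = sub.sample_interval
    n = len(x)
    if n * dt < MIN_DURATION:
        raise SegmentTooShortError(
            f"segment lasts {n * dt:.1f} s; need at least {MIN_DURATION} s "
            "for 0.1 Hz frequency resolution")
    x = x - np.mean(x)
    w = hann(n)
    spec = np.fft.rfft(w * x)
    power = np.abs(spec) ** 2
    # One-sided: double everything except DC (and Nyquist for even n).
    if n % 2 == 0:
        power[1:-1] *= 2.0
    else:
        power[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, dt)
    if normalize:
        band = (freqs >= BAND[0]) & (freqs <= BAND[1])
        total = power[band].sum()
        if total > 0:
            power = power / total
    return freqs, power


def dominant_frequencies(freqs: np.ndarray, power: np.ndarray,
                         n_peaks: int = 3, prominence_frac: float = 0.05,
                         ) -> SpectralPeaks:
    """Extract the dominant in-band peaks, ordered by ascending frequency.

    Local maxima within 0.3–6 Hz with prominence at least
    ``prominence_frac`` times the in-band maximum qualify; the ``n_peaks``
    largest by power are kept.  If fewer qualify, the missing slots are NaN.
    """
    band = (freqs >= BAND[0]) & (freqs <= BAND[1])
    f_band, p_band = freqs[band], power[band]
    if p_band.size == 0 or p_band.max() <= 0:
        return SpectralPeaks(*([np.nan] * 6), n_found=0)
    idx, _ = find_peaks(p_band, prominence=prominence_frac * p_band.max())
    order = idx[np.argsort(p_band[idx])[::-1][:n_peaks]]
    chosen = np.sort(order)
    fs = [np.nan] * n_peaks
    amps = [np.nan] * n_peaks
    for slot, i in enumerate(chosen):
        fs[slot] = float(f_band[i])
        amps[slot] = float(p_band[i])
    return SpectralPeaks(fs[0], fs[1], fs[2], amps[0], amps[1], amps[2],
                         n_found=len(chosen))
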