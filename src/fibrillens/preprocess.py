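"""Zero-phase band-pass prefiltering and R-peak detection.

The prefilter is the 6th-order Butterworth band-pass (0.5-45 Hz) applied
forward and backward, so the effective magnitude response is the squared
one-pass response and the phase is zero. R peaks are found with a
Pan-Tompkins-style chain (band-limited energy -> derivative -> squaring ->
moving-window integration -> adaptive thresholding), then refined to the
local extremum of the absolute filtered signal so that detection is
polarity-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import FilteringError, ValidationError


@dataclass
class RPeakSeries:
    """Detected R-peak sample positions at a given sampling rate."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size >= 2 and not np.all(np.diff(self.indices) > 0):
            raise ValidationError("R-peak indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)


def bandpass_filter(
    samples,
    fs: float,
    low_hz: float = 0.5,
    high_hz: float = 45.0,
    order: int = 6,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass; output length equals input length.

    ``order`` is the design order of the one-pass filter; the bidirectional
    application squares its magnitude response.
    """
    x = np.asarray(samples, dtype=float)
    if fs <= 2 * high_hz:
        raise ValidationError(
            f"sampling rate {fs} Hz leaves no room above the {high_hz} Hz cutoff"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    # sosfiltfilt needs enough samples for its edge padding
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum()))
    if x.size <= padlen or x.size <= 3 * order:
        raise FilteringError(f"record too short to filter ({x.size} samples)")
    return signal.sosfiltfilt(sos, x)


def _refine_to_extremum(absx: np.ndarray, idx: int, radius: int) -> int:
    """Move ``idx`` to the local maximum of ``absx`` within +-radius.

    Iterated to a fixed point, which makes refinement idempotent.
    """
    n = absx.size
    for _ in range(10):
        lo = max(0, idx - radius)
        hi = min(n, idx + radius + 1)
        new = lo + int(np.argmax(absx[lo:hi]))
        if new == idx:
            break
        idx = new
    return idx


def detect_rpeaks(
    filtered,
    fs: float,
    refractory_ms: float = 200.0,
    refine_ms: float = 40.0,
    integration_ms: float = 150.0,
    enhance_low_hz: float = 5.0,
    enhance_high_hz: float = 25.0,
) -> RPeakSeries:
    """Pan-Tompkins-style QRS detection on a prefiltered signal.

    May return an empty series (a flat record has no peaks); it never raises
    for signal content.
    """
    x = np.asarray(filtered, dtype=float)
    if x.size < int(0.5 * fs) or not np.any(x):
        return RPeakSeries(np.array([], dtype=int), fs)

    # QRS enhancement: band-limit, differentiate, square, integrate
    sos = signal.butter(
        2, [enhance_low_hz, enhance_high_hz], btype="bandpass", fs=fs, output="sos"
    )
    e = signal.sosfiltfilt(sos, x)
    d = np.gradient(e)
    sq = d * d
    win = max(1, int(round(integration_ms / 1000.0 * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    dist = max(1, int(round(refractory_ms / 1000.0 * fs)))
    cand, _ = signal.find_peaks(mwi, distance=dist)
    if cand.size == 0:
        return RPeakSeries(np.array([], dtype=int), fs)

    # adaptive signal/noise level recursion (SPKI / NPKI)
    lead = mwi[: int(min(mwi.size, 2 * fs))]
    spki = 0.25 * float(np.max(lead))
    npki = 0.5 * float(np.mean(lead))
    kept: list[int] = []
    for p in cand:
        thr = npki + 0.25 * (spki - npki)
        if mwi[p] > thr:
            kept.append(int(p))
            spki = 0.125 * mwi[p] + 0.875 * spki
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki

    # refine to the extremum of |signal| within +-refine_ms
    absx = np.abs(x)
    radius = max(1, int(round(refine_ms / 1000.0 * fs)))
    refined = sorted({_refine_to_extremum(absx, p, radius) for p in kept})

    # enforce the refractory period after refinement (keep the larger peak)
    final: list[int] = []
    for p in refined:
        if final and p - final[-1] < dist:
            if absx[p] > absx[final[-1]]:
                final[-1] = p
        else:
            final.append(p)
    return RPeakSeries(np.asarray(final, dtype=int), fs)
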