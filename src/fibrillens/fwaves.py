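"""Residual ECG via segmented beat modulation and the four FWFR features.

The dominant (repetitive) waveform of the recording is estimated with the
segmented beat modulation principle: each cardiac cycle is split into a
fixed-duration QRS segment and a TUP segment that is linearly stretched to
the median-RR TUP length; the per-sample median over the normalised cycles
is the beat template, which is then stretched back to each cycle's own
length and stitched into a dominant signal. Subtracting it from the ECG
leaves the residual, whose atrial content (fibrillatory waves) survives
because it is asynchronous with the ventricular beat template.

The F-waves frequency ratio (FWFR) is the spectral area of the residual in
the 4-10 Hz fibrillatory band over the total spectral area, computed with
four power-spectral-density estimators: raw periodogram (FFT), Welch (WLC),
Yule-Walker autoregressive (YWK) and Thomson multitaper (THM).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import signal

from .errors import ConstructionError, DegenerateSignalError, EstimationError, ValidationError
from .preprocess import RPeakSeries

F_BAND = (4.0, 10.0)

PSD_METHODS = ("FFT", "WLC", "YWK", "THM")


class FwfrFeatures(NamedTuple):
    """The four spectral-ratio features, as fractions in [0, 1]."""

    FWFR_FFT: float
    FWFR_WLC: float
    FWFR_YWK: float
    FWFR_THM: float


def _stretch(seg: np.ndarray, length: int) -> np.ndarray:
    """Linear resampling of ``seg`` to ``length`` samples."""
    if length <= 0:
        return np.empty(0)
    if seg.size == 0:
        return np.zeros(length)
    if seg.size == 1:
        return np.full(length, seg[0])
    src = np.linspace(0.0, 1.0, seg.size)
    dst = np.linspace(0.0, 1.0, length)
    return np.interp(dst, src, seg)


def sbmm_dominant(
    samples,
    rpeaks,
    fs: float,
    t_pre_ms: float = 100.0,
    t_qrs_ms: float = 140.0,
) -> np.ndarray:
    """Dominant ECG waveform by segmented beat modulation.

    Cycles span ``[R_i - T_pre, R_{i+1} - T_pre)``. The first ``T_qrs`` of
    each cycle (the QRS segment) is kept at fixed duration; the remaining
    TUP segment is stretched to the median-RR TUP length before the
    per-sample median template is taken, and the template TUP is stretched
    back when the dominant signal is reconstructed. Samples not covered by
    any full cycle (head and tail) copy the input, i.e. contribute zero
    residual.
    """
    x = np.asarray(samples, dtype=float)
    if isinstance(rpeaks, RPeakSeries):
        rpeaks = rpeaks.indices
    r = np.asarray(rpeaks, dtype=int)
    if r.size < 3:
        raise ConstructionError("need at least three R peaks (two RR intervals)")
    pre = int(round(t_pre_ms / 1000.0 * fs))
    qrs_n = int(round(t_qrs_ms / 1000.0 * fs))

    starts = r - pre
    bounds = [
        (int(starts[i]), int(starts[i + 1]))
        for i in range(r.size - 1)
        if starts[i] >= 0 and starts[i + 1] <= x.size
    ]
    if len(bounds) < 2:
        raise ConstructionError("fewer than two complete cardiac cycles in record")

    lens = np.array([e - s for s, e in bounds])
    med_len = int(round(float(np.median(lens))))
    med_tup = max(med_len - qrs_n, 0)

    normalised = []
    for s, e in bounds:
        cyc = x[s:e]
        q = cyc[: min(qrs_n, cyc.size)]
        if q.size < qrs_n:  # degenerate short cycle: pad with its last value
            q = np.concatenate([q, np.full(qrs_n - q.size, q[-1] if q.size else 0.0)])
        tup = cyc[qrs_n:]
        normalised.append(np.concatenate([q, _stretch(tup, med_tup)]))
    template = np.median(np.vstack(normalised), axis=0)

    dominant = x.copy()
    for s, e in bounds:
        cyc_len = e - s
        nq = min(qrs_n, cyc_len)
        dominant[s : s + nq] = template[:nq]
        if cyc_len > qrs_n:
            dominant[s + qrs_n : e] = _stretch(template[qrs_n:], cyc_len - qrs_n)
    return dominant


def residual(samples, dominant) -> np.ndarray:
    """Residual ECG: elementwise difference of record and dominant waveform."""
    x = np.asarray(samples, dtype=float)
    d = np.asarray(dominant, dtype=float)
    if x.shape != d.shape:
        raise ValidationError("record and dominant waveform lengths differ")
    return x - d


def estimate_psd(
    res,
    fs: float,
    method: str = "WLC",
    welch_nperseg: int = 1024,
    ar_order: int = 16,
    multitaper_nw: float = 4.0,
    multitaper_k: int = 7,
    n_freqs: int = 2049,
    detrend: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided PSD of the residual on [0, fs/2].

    ``method`` is one of FFT (Hamming-tapered periodogram), WLC (Welch,
    1024-sample segments, 50% overlap, Hamming), YWK (Yule-Walker AR(16))
    or THM (Thomson multitaper, time-bandwidth 4, 7 tapers). The residual
    is linearly detrended first to suppress stitching artefacts at cycle
    boundaries.
    """
    x = np.asarray(res, dtype=float)
    min_len = max(64, 2 * ar_order + 2)
    if x.size < min_len:
        raise EstimationError(f"residual too short for PSD estimation ({x.size})")
    if detrend:
        x = signal.detrend(x)

    if method == "FFT":
        f, p = signal.periodogram(x, fs=fs, window="hamming")
    elif method == "WLC":
        nper = min(welch_nperseg, x.size)
        f, p = signal.welch(x, fs=fs, window="hamming", nperseg=nper, noverlap=nper // 2)
    elif method == "YWK":
        from statsmodels.regression.linear_model import yule_walker

        rho, sigma = yule_walker(x, order=ar_order, method="mle")
        f, h = signal.freqz(
            1.0, np.concatenate([[1.0], -rho]), worN=n_freqs, fs=fs,
            include_nyquist=True,
        )
        p = 2.0 * sigma**2 / fs * np.abs(h) ** 2
        p[0] /= 2.0
        p[-1] /= 2.0
    elif method == "THM":
        tapers = signal.windows.dpss(x.size, multitaper_nw, Kmax=multitaper_k)
        spec = np.abs(np.fft.rfft(tapers * x[None, :], axis=1)) ** 2
        p = 2.0 * spec.mean(axis=0) / fs
        p[0] /= 2.0
        if x.size % 2 == 0:
            p[-1] /= 2.0
        f = np.fft.rfftfreq(x.size, d=1.0 / fs)
    else:
        raise ValidationError(f"unknown PSD method {method!r}")
    return f, np.maximum(p, 0.0)


def _band_area(f: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal area of the density between lo and hi Hz."""
    lo = max(lo, float(f[0]))
    hi = min(hi, float(f[-1]))
    if hi <= lo:
        return 0.0
    inner = (f > lo) & (f < hi)
    ff = np.concatenate([[lo], f[inner], [hi]])
    pp = np.concatenate([[np.interp(lo, f, p)], p[inner], [np.interp(hi, f, p)]])
    return float(np.trapezoid(pp, ff))


def fwfr(
    f,
    p,
    band: tuple[float, float] = F_BAND,
    total_band: tuple[float, float] | None = None,
) -> float:
    """F-waves frequency ratio: band area over total spectral area, in [0, 1].

    The total area spans the full [0, fs/2] grid unless ``total_band``
    restricts it (e.g. to the 0.5-45 Hz prefilter band).
    """
    f = np.asarray(f, dtype=float)
    p = np.asarray(p, dtype=float)
    if f.size != p.size or f.size < 2:
        raise ValidationError("frequency grid and density must match and be non-trivial")
    if total_band is None:
        total = float(np.trapezoid(p, f))
    else:
        total = _band_area(f, p, *total_band)
    if total <= 0.0:
        raise DegenerateSignalError("zero total spectral area")
    ratio = _band_area(f, p, *band) / total
    return float(min(max(ratio, 0.0), 1.0))


def fwfr_features(
    res, fs: float, total_band: tuple[float, float] | None = None, **psd_kwargs
) -> FwfrFeatures:
    """All four FWFR values of a residual ECG."""
    vals = []
    for m in PSD_METHODS:
        f, p = estimate_psd(res, fs, method=m, **psd_kwargs)
        vals.append(fwfr(f, p, total_band=total_band))
    return FwfrFeatures(*vals)
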