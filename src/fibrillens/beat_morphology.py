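"""Median beat, six-landmark delineation and the 11 morphological features.

The median ECG beat (MECGB) is the per-sample median of fixed windows
spanning 250 ms before to 450 ms after each detected R peak (211 samples at
300 Hz). Six fiducial landmarks are located on it:

* ``Rp``  - absolute maximum of |MECGB|;
* ``QRSon``  - second-to-last sign change of the MECGB derivative before Rp;
* ``QRSoff`` - second sign change after Rp (the J point);
* ``Pp``  - absolute maximum of |MECGB| left of QRSon (P peak, or the
  highest fibrillatory oscillation when no P wave exists);
* ``Tp``  - absolute maximum of |MECGB| right of QRSoff;
* ``Toff`` - first derivative sign change after Tp.

Derivative sign changes are evaluated on a lightly smoothed copy of the
median beat with a small relative dead band, so that flat segments (and
negligible wiggles within them) do not create spurious landmarks; amplitudes
are always read off the raw median beat.

A zero-phase 0.5 Hz high-pass removes the periodic mean of the beat train,
so the filtered median beat rides at an isoelectric level below zero.  The
``Pp`` and ``Tp`` absolute-maximum searches therefore reference the beat to
its baseline sample (80 ms before Rp) first; otherwise isoelectric samples
would outweigh a genuine P wave.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import DelineationError, ValidationError
from .preprocess import RPeakSeries

PRE_MS = 250.0
POST_MS = 450.0
BASELINE_MS = 80.0


@dataclass
class MedianBeat:
    waveform: np.ndarray
    r_offset: int
    fs: float

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)


@dataclass
class Landmarks:
    """Sample offsets of the six fiducial points within the median beat."""

    Pp: int
    Rp: int
    Tp: int
    QRSon: int
    QRSoff: int
    Toff: int

    def ordered(self) -> bool:
        return self.Pp < self.QRSon < self.Rp < self.QRSoff < self.Tp < self.Toff


@dataclass
class MorphFeatures:
    PpRp: float  # ms
    PpQRSoff: float  # ms
    QRSonQRSoff: float  # ms
    QRSonToff: float  # ms
    QRSoffToff: float  # ms
    AP: float  # uV
    AQRSon: float  # uV
    AQRS: float  # uV
    AQRSoff: float  # uV
    AT: float  # uV
    AQRS_over_AP: float  # dimensionless

    def to_dict(self) -> dict[str, float]:
        d = {
            "PpRp": self.PpRp,
            "PpQRSoff": self.PpQRSoff,
            "QRSonQRSoff": self.QRSonQRSoff,
            "QRSonToff": self.QRSonToff,
            "QRSoffToff": self.QRSoffToff,
            "AP": self.AP,
            "AQRSon": self.AQRSon,
            "AQRS": self.AQRS,
            "AQRSoff": self.AQRSoff,
            "AT": self.AT,
            "AQRS/AP": self.AQRS_over_AP,
        }
        return d


def window_lengths(fs: float) -> tuple[int, int]:
    """(samples before R, samples after R) of the beat window."""
    return int(round(PRE_MS / 1000.0 * fs)), int(round(POST_MS / 1000.0 * fs))


def extract_beat_segments(samples, rpeaks, fs: float) -> np.ndarray:
    """Stack the fixed beat windows fully contained in the record.

    Returns an array of shape (n_beats, pre+post+1); windows that would
    leave the record are dropped.
    """
    x = np.asarray(samples, dtype=float)
    if isinstance(rpeaks, RPeakSeries):
        rpeaks = rpeaks.indices
    r = np.asarray(rpeaks, dtype=int)
    if r.size < 1:
        raise DelineationError("no R peaks to segment around")
    pre, post = window_lengths(fs)
    rows = [x[p - pre : p + post + 1] for p in r if p - pre >= 0 and p + post < x.size]
    if not rows:
        raise DelineationError("no beat window fits inside the record")
    return np.vstack(rows)


def median_beat(segments, fs: float = 300.0) -> MedianBeat:
    """Per-sample median of equal-length beat segments.

    An even number of beats uses the mean of the two central order
    statistics (numpy convention).
    """
    if isinstance(segments, np.ndarray) and segments.ndim == 2:
        seg = segments
    else:
        rows = [np.asarray(s, dtype=float) for s in segments]
        if not rows:
            raise ValidationError("no segments")
        if len({r.size for r in rows}) != 1:
            raise ValidationError("segments must have equal lengths")
        seg = np.vstack(rows)
    if seg.shape[0] < 1:
        raise ValidationError("no segments")
    pre, _ = window_lengths(fs)
    return MedianBeat(np.median(seg, axis=0), r_offset=pre, fs=fs)


def _sign_changes(d: np.ndarray, deadband: float) -> np.ndarray:
    """Indices i where the derivative changes sign, zero runs skipped.

    Values with |d| <= deadband are treated as zero. The reported position
    is the sample at which the new slope begins, i.e. the extremum (or the
    end of a plateau).
    """
    sgn = np.where(d > deadband, 1, np.where(d < -deadband, -1, 0))
    changes = []
    prev = 0
    for i, s in enumerate(sgn):
        if s == 0:
            continue
        if prev != 0 and s != prev:
            changes.append(i)
        prev = s
    return np.asarray(changes, dtype=int)


def _argmax_near(absw: np.ndarray, lo: int, hi: int, anchor: int) -> int:
    """argmax of absw[lo:hi], ties broken toward the sample nearest anchor."""
    win = absw[lo:hi]
    m = win.max()
    ties = np.flatnonzero(win == m) + lo
    return int(ties[np.argmin(np.abs(ties - anchor))])


def find_landmarks(
    mb: MedianBeat,
    smooth_window: int = 11,
    smooth_poly: int = 3,
    deadband_frac: float = 0.002,
) -> Landmarks:
    """Locate the six fiducial landmarks on a median beat.

    Raises :class:`DelineationError` (naming the missing landmark) when a
    required derivative sign change does not exist, e.g. on a monotone tail.
    """
    w = mb.waveform
    if w.size < smooth_window + 2:
        raise DelineationError("median beat too short to delineate")
    if smooth_window > 2:
        ws = savgol_filter(w, smooth_window, min(smooth_poly, smooth_window - 1))
    else:
        ws = w
    absw = np.abs(w)
    rp = _argmax_near(absw, 0, w.size, anchor=int(np.argmax(absw)))

    # baseline-referenced amplitudes for the P/T searches (see module docs)
    b_idx = max(0, rp - int(round(BASELINE_MS / 1000.0 * mb.fs)))
    absw_ref = np.abs(w - w[b_idx])

    d = np.diff(ws)
    deadband = deadband_frac * float(np.max(np.abs(d))) if d.size else 0.0
    changes = _sign_changes(d, deadband)

    before = changes[changes < rp]
    if before.size < 2:
        raise DelineationError("QRS onset not found before R peak", landmark="QRSon")
    qrs_on = int(before[-2])

    after = changes[changes > rp]
    if after.size < 2:
        raise DelineationError("QRS offset not found after R peak", landmark="QRSoff")
    qrs_off = int(after[1])

    if qrs_on < 1:
        raise DelineationError("no room left of QRS onset for P peak", landmark="Pp")
    pp = _argmax_near(absw_ref, 0, qrs_on, anchor=rp)

    if qrs_off + 1 >= w.size:
        raise DelineationError("no room right of QRS offset for T peak", landmark="Tp")
    tp = _argmax_near(absw_ref, qrs_off + 1, w.size, anchor=rp)

    later = changes[changes > tp]
    if later.size < 1:
        raise DelineationError("T offset not found after T peak", landmark="Toff")
    toff = int(later[0])

    return Landmarks(Pp=pp, Rp=rp, Tp=tp, QRSon=qrs_on, QRSoff=qrs_off, Toff=toff)


def morphological_features(
    mb: MedianBeat,
    lm: Landmarks,
    fs: float | None = None,
    baseline_mode: str = "point",
    ap_eps: float = 1e-6,
    ratio_cap: float = 1e4,
) -> MorphFeatures:
    """The 11 morphological features of the feature table.

    Time intervals are in ms; amplitudes in uV relative to the baseline
    sample taken 80 ms before Rp (``baseline_mode="mean3"`` averages the
    three samples centred there). AQRS is the max-min excursion over
    [QRSon, QRSoff] and needs no baseline. When |AP| falls below ``ap_eps``
    the AQRS/AP ratio is capped at +-``ratio_cap`` so downstream
    normalisation stays finite.
    """
    fs = mb.fs if fs is None else fs
    w = mb.waveform
    ms = 1000.0 / fs

    b_idx = lm.Rp - int(round(BASELINE_MS / 1000.0 * fs))
    if b_idx < 0:
        raise ValidationError("baseline sample (80 ms before Rp) outside the window")
    if baseline_mode == "mean3":
        b = float(np.mean(w[max(0, b_idx - 1) : b_idx + 2]))
    else:
        b = float(w[b_idx])

    ap = float(w[lm.Pp] - b)
    aqrs = float(np.max(w[lm.QRSon : lm.QRSoff + 1]) - np.min(w[lm.QRSon : lm.QRSoff + 1]))
    if abs(ap) < ap_eps:
        ratio = ratio_cap if ap >= 0 else -ratio_cap
    else:
        ratio = aqrs / ap

    return MorphFeatures(
        PpRp=(lm.Rp - lm.Pp) * ms,
        PpQRSoff=(lm.QRSoff - lm.Pp) * ms,
        QRSonQRSoff=(lm.QRSoff - lm.QRSon) * ms,
        QRSonToff=(lm.Toff - lm.QRSon) * ms,
        QRSoffToff=(lm.Toff - lm.QRSoff) * ms,
        AP=ap,
        AQRSon=float(w[lm.QRSon] - b),
        AQRS=aqrs,
        AQRSoff=float(w[lm.QRSoff] - b),
        AT=float(w[lm.Tp] - b),
        AQRS_over_AP=ratio,
    )
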