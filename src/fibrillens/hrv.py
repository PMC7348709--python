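"""RR-interval series and the four heart-rate-variability features.

* ``MRR``   mean RR interval (ms)
* ``SDRR``  sample standard deviation of the RR intervals (ms)
* ``RMSRR`` root mean square of successive RR differences (ms); a literal
  RMS-of-the-intervals mode exists but the successive-difference reading is
  the default, being the only one compatible with the magnitudes such a
  statistic takes on real data (tens of ms against a mean interval near a
  second)
* ``PRR50`` percentage of beats whose RR exceeds the previous RR by more
  than 50 ms (the "as-written", increase-only count); ``mode="absolute"``
  gives the conventional pNN50 on |successive difference| > 50 ms
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .errors import ValidationError
from .preprocess import RPeakSeries


class HRVFeatures(NamedTuple):
    MRR: float
    SDRR: float
    RMSRR: float
    PRR50: float


def rr_series(rpeaks, fs: float | None = None) -> np.ndarray:
    """Successive RR intervals in ms from R-peak sample positions."""
    if isinstance(rpeaks, RPeakSeries):
        fs = rpeaks.fs if fs is None else fs
        rpeaks = rpeaks.indices
    if fs is None:
        raise ValidationError("sampling rate required")
    r = np.asarray(rpeaks, dtype=float)
    if r.size < 2:
        raise ValidationError("need at least two R peaks for an RR series")
    if not np.all(np.diff(r) > 0):
        raise ValidationError("R-peak positions must be strictly increasing")
    return np.diff(r) * 1000.0 / fs


def hrv_features(
    rr, prr50_mode: str = "as-written", rmsrr_mode: str = "successive"
) -> HRVFeatures:
    """The four HRV features from an RR series in ms."""
    x = np.asarray(rr, dtype=float)
    if x.size < 1:
        raise ValidationError("empty RR series")
    if np.any(x <= 0):
        raise ValidationError("RR intervals must be positive")
    mrr = float(np.mean(x))
    if x.size < 2:
        raise ValidationError("need at least two RR intervals for SDRR/RMSRR/PRR50")
    sdrr = float(np.std(x, ddof=1))
    diffs = np.diff(x)
    if rmsrr_mode == "successive":
        rmsrr = float(np.sqrt(np.mean(diffs**2)))
    elif rmsrr_mode == "literal":
        rmsrr = float(np.sqrt(np.mean(x**2)))
    else:
        raise ValidationError(f"unknown rmsrr_mode {rmsrr_mode!r}")
    if prr50_mode == "as-written":
        count = int(np.sum(diffs > 50.0))
    elif prr50_mode == "absolute":
        count = int(np.sum(np.abs(diffs) > 50.0))
    else:
        raise ValidationError(f"unknown prr50_mode {prr50_mode!r}")
    prr50 = 100.0 * count / diffs.size
    return HRVFeatures(mrr, sdrr, rmsrr, prr50)
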