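"""Ground-truth synthetic single-lead ECG generator.

Each beat is a sum of Gaussian waves. Besides the textbook P-QRS-T
complex the template carries three small ventricular details - a pre-Q
shoulder, a J wave after S, and a U wave after T - so every derivative
sign change the delineator relies on (second-to-last before Rp, second
after Rp, first after Tp) has a well-defined physiologic target, and that
target is identical in AF and non-AF records because the ventricular
complex is unaffected by atrial fibrillation.

AF mode removes the P wave, adds an amplitude-modulated, slowly
frequency-drifting sinusoid in the 4-10 Hz fibrillatory band (the drift
and per-record random phase keep it asynchronous with the beat template,
so beat-median subtraction cannot absorb it), and inflates the RR
coefficient of variation. RR intervals are gamma distributed; broadband
Gaussian noise is added at a configurable SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io_dataset import AF, ECGRecord, NON_AF

#: (amplitude uV, centre ms relative to R, width sigma ms)
DEFAULT_WAVES: dict[str, tuple[float, float, float]] = {
    "P": (120.0, -170.0, 20.0),
    "preQ": (35.0, -42.0, 8.0),
    "Q": (-90.0, -20.0, 6.0),
    "R": (1000.0, 0.0, 9.0),
    "S": (-140.0, 20.0, 6.0),
    "J": (45.0, 48.0, 10.0),
    "T": (320.0, 270.0, 42.0),
    "U": (45.0, 430.0, 22.0),
}

#: minimum physiologic RR interval (ventricular refractoriness), ms
RR_FLOOR_MS = 300.0


@dataclass
class SynthParams:
    """Generator settings; class defaults come from :meth:`for_class`."""

    fs: float = 300.0
    duration_s: float = 30.0
    rr_mean_ms: float = 860.0
    rr_cv: float = 0.03
    af: bool = False
    f_wave_amp_uv: float = 40.0
    f_wave_freq_hz: float = 7.0
    f_freq_drift_hz: float = 0.4
    f_am_depth: float = 0.3
    noise_snr_db: float = 15.0
    waves: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WAVES)
    )

    @classmethod
    def for_class(cls, af: bool, **overrides) -> "SynthParams":
        """Default study conditions for one class.

        Non-AF: mean RR 860 ms, cv 0.03. AF: mean RR 720 ms, cv 0.20 -
        chosen so SDRR magnitudes land in the ranges observed on real
        short-lead recordings (tens of ms against ~150 ms).
        """
        if af:
            base = cls(af=True, rr_mean_ms=720.0, rr_cv=0.20)
        else:
            base = cls(af=False)
        return replace(base, **overrides)

    def validate(self) -> None:
        if self.fs <= 90:
            raise ValidationError("sampling rate must exceed 90 Hz")
        if self.duration_s <= 0:
            raise ValidationError("duration must be positive")
        if self.rr_mean_ms < RR_FLOOR_MS:
            raise ValidationError(
                f"mean RR {self.rr_mean_ms} ms shorter than the {RR_FLOOR_MS} ms floor"
            )
        if self.af and not (4.0 <= self.f_wave_freq_hz <= 10.0):
            raise ValidationError("F-wave frequency must lie in the 4-10 Hz band")
        if not all(np.isfinite([a for a, _, _ in self.waves.values()])):
            raise ValidationError("wave amplitudes must be finite")


@dataclass
class GroundTruth:
    """What the generator actually produced, for oracle tests."""

    r_indices: np.ndarray  # true R sample positions
    rr_ms: np.ndarray  # the RR sequence that placed them
    landmarks_ms: dict[str, float] | None  # per-beat truth, offsets from R in ms
    label: str


def beat_template(t_ms, waves: dict[str, tuple[float, float, float]]) -> np.ndarray:
    """Clean beat waveform at times ``t_ms`` (ms relative to the R peak)."""
    t = np.asarray(t_ms, dtype=float)
    y = np.zeros_like(t)
    for amp, centre, sigma in waves.values():
        y += amp * np.exp(-0.5 * ((t - centre) / sigma) ** 2)
    return y


def _dense_extremum(
    waves: dict, lo: float, hi: float, mode: str, step: float = 0.05
) -> float:
    """Location (ms) of the max/min of the clean template on [lo, hi]."""
    t = np.arange(lo, hi + step, step)
    y = beat_template(t, waves)
    i = int(np.argmax(y) if mode == "max" else np.argmin(y))
    return float(t[i])


def true_landmarks_ms(waves: dict[str, tuple[float, float, float]]) -> dict[str, float]:
    """Independent landmark truth from the continuous beat model.

    Each landmark is the dense-grid extremum of the noiseless template in a
    window bracketing the responsible wave: Pp and Tp are the P and T peaks,
    QRSon the pre-Q shoulder crest, QRSoff the J-wave crest, Toff the T-U
    valley, Rp the global maximum.
    """
    _, p_c, p_s = waves["P"]
    _, q_c, _ = waves["Q"]
    _, s_c, _ = waves["S"]
    _, j_c, j_s = waves["J"]
    _, t_c, t_s = waves["T"]
    _, u_c, _ = waves["U"]
    return {
        "Pp": _dense_extremum(waves, p_c - 2 * p_s, p_c + 2 * p_s, "max"),
        "QRSon": _dense_extremum(waves, p_c + 2.5 * p_s, q_c - 3.0, "max"),
        "Rp": _dense_extremum(waves, -30.0, 30.0, "max"),
        "QRSoff": _dense_extremum(waves, s_c + 8.0, j_c + 3 * j_s, "max"),
        "Tp": _dense_extremum(waves, t_c - 2 * t_s, t_c + 2 * t_s, "max"),
        "Toff": _dense_extremum(waves, t_c + t_s, u_c, "min"),
    }


def _draw_rr_sequence(params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """Gamma-distributed RR intervals (ms), floored at the refractory RR."""
    n_max = int(np.ceil(params.duration_s * 1000.0 / RR_FLOOR_MS)) + 2
    if params.rr_cv <= 0:
        rr = np.full(n_max, params.rr_mean_ms)
    else:
        shape = 1.0 / params.rr_cv**2
        scale = params.rr_mean_ms * params.rr_cv**2
        rr = rng.gamma(shape, scale, size=n_max)
    return np.maximum(rr, RR_FLOOR_MS)


def synth_record(
    params: SynthParams, seed: int, record_id: str | None = None
) -> tuple[ECGRecord, GroundTruth]:
    """Generate one record plus its ground truth; reproducible by seed."""
    params.validate()
    rng = np.random.default_rng(seed)
    fs = params.fs
    n = int(round(fs * params.duration_s))
    t_ms = np.arange(n) * 1000.0 / fs

    waves = dict(params.waves)
    if params.af:
        waves.pop("P", None)

    rr = _draw_rr_sequence(params, rng)
    first = 400.0 + rng.uniform(0.0, rr[0] / 2)
    beat_times = [first]
    for interval in rr[1:]:
        nxt = beat_times[-1] + interval
        if nxt > params.duration_s * 1000.0 - 150.0:
            break
        beat_times.append(nxt)
    beat_times = np.asarray(beat_times)

    x = np.zeros(n)
    half_span = 520.0  # ms; beyond this every Gaussian tail is negligible
    for bt in beat_times:
        lo = max(0, int(np.floor((bt - half_span) * fs / 1000.0)))
        hi = min(n, int(np.ceil((bt + half_span) * fs / 1000.0)) + 1)
        x[lo:hi] += beat_template(t_ms[lo:hi] - bt, waves)

    if params.af:
        t_s = t_ms / 1000.0
        drift_phase = rng.uniform(0.0, 2 * np.pi)
        f_inst = params.f_wave_freq_hz + params.f_freq_drift_hz * np.sin(
            2 * np.pi * 0.05 * t_s + drift_phase
        )
        f_inst = np.clip(f_inst, 4.0, 10.0)
        phase = 2 * np.pi * np.cumsum(f_inst) / fs + rng.uniform(0.0, 2 * np.pi)
        am = 1.0 + params.f_am_depth * np.sin(
            2 * np.pi * 0.1 * t_s + rng.uniform(0.0, 2 * np.pi)
        )
        x = x + params.f_wave_amp_uv * am * np.sin(phase)

    if np.isfinite(params.noise_snr_db):
        rms = float(np.sqrt(np.mean(x**2)))
        sigma = rms / 10.0 ** (params.noise_snr_db / 20.0)
        x = x + rng.normal(0.0, sigma, size=n)

    r_indices = np.round(beat_times * fs / 1000.0).astype(int)
    r_indices = r_indices[r_indices < n]
    truth = GroundTruth(
        r_indices=r_indices,
        rr_ms=np.diff(beat_times),
        landmarks_ms=None if params.af else true_landmarks_ms(waves),
        label=AF if params.af else NON_AF,
    )
    record = ECGRecord(
        record_id=record_id or ("synthetic-af" if params.af else "synthetic-nonaf"),
        fs=fs,
        samples=x,
        label=truth.label,
        raw_annotation="A" if params.af else "N",
    )
    return record, truth


def _jitter_params(
    base: SynthParams, rng: np.random.Generator
) -> SynthParams:
    """Per-record physiologic variability around the class defaults."""
    waves = {}
    global_gain = rng.uniform(0.8, 1.2)
    for name, (amp, centre, sigma) in base.waves.items():
        waves[name] = (
            amp * global_gain * rng.uniform(0.95, 1.05),
            centre + rng.uniform(-4.0, 4.0),
            sigma * rng.uniform(0.9, 1.1),
        )
    return replace(
        base,
        rr_mean_ms=max(base.rr_mean_ms * rng.uniform(0.85, 1.15), RR_FLOOR_MS),
        rr_cv=base.rr_cv * rng.uniform(0.7, 1.4),
        f_wave_freq_hz=rng.uniform(4.5, 9.5),
        f_wave_amp_uv=base.f_wave_amp_uv * rng.uniform(0.7, 1.4),
        noise_snr_db=base.noise_snr_db + rng.uniform(-3.0, 3.0),
        waves=waves,
    )


def make_dataset(
    n_af: int,
    n_nonaf: int,
    params: SynthParams | None = None,
    seed: int = 0,
    af_params: SynthParams | None = None,
) -> list[tuple[ECGRecord, GroundTruth]]:
    """Independent labelled records with per-record jittered parameters.

    ``params`` overrides the non-AF defaults, ``af_params`` the AF defaults;
    class counts are exact.
    """
    if n_af < 0 or n_nonaf < 0:
        raise ValidationError("record counts must be non-negative")
    if n_af + n_nonaf == 0:
        raise ValidationError("at least one record must be requested")
    base_non = params or SynthParams.for_class(False)
    base_af = af_params or SynthParams.for_class(True)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_af + n_nonaf)
    out = []
    for i in range(n_af + n_nonaf):
        af = i < n_af
        child = np.random.default_rng(children[i])
        p = _jitter_params(base_af if af else base_non, child)
        rec_seed = int(children[i].generate_state(1)[0] % 2**31)
        rid = f"S{i:05d}"
        out.append(synth_record(p, rec_seed, record_id=rid))
    return out


def write_dataset(
    dataset: Sequence[tuple[ECGRecord, GroundTruth]], directory: str | Path
) -> Path:
    """Write records in the CSV dialect plus a REFERENCE.csv label file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, _truth in dataset:
        np.savetxt(directory / f"{rec.record_id}.csv", rec.samples, fmt="%.4f")
        rows.append(f"{rec.record_id},{rec.raw_annotation}")
    (directory / "REFERENCE.csv").write_text("\n".join(rows) + "\n")
    return directory
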