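"""Record and label I/O, SNR characterisation, acceptance gate, dataset splits.

Two on-disk dialects are supported:

``wfdb2017``
    One WFDB header (``<id>.hea``) per record plus a sample file, as in the
    PhysioNet "AF Classification from a Short Single Lead ECG Recording"
    distribution (MAT sample files with a ``val`` variable, or raw int16).
    Labels live in a two-column, headerless ``REFERENCE.csv`` mapping record
    id to one of the challenge codes ``N``, ``A``, ``O``, ``~``.

``csv``
    One amplitude per line; the sampling rate is supplied by the caller.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DegenerateSignalError, ReadError, ValidationError

#: challenge annotation codes and the two-class labels used throughout
AF = "AF"
NON_AF = "nonAF"
CHALLENGE_CODES = ("N", "A", "O", "~")


@dataclass
class ECGRecord:
    """One labelled single-lead ECG recording.

    Amplitudes are stored in microvolts (for WFDB input the header gain is
    applied on read; CSV input is taken to be in physical units already).
    """

    record_id: str
    fs: float
    samples: np.ndarray
    label: str | None = None  # "AF" / "nonAF" / None (unlabeled)
    raw_annotation: str | None = None  # one of N, A, O, ~ or None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError("samples must be one-dimensional")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class DatasetSplit:
    """Disjoint train / validation / test id sets."""

    train_ids: list[str]
    validation_ids: list[str]
    test_ids: list[str]
    fractions: tuple[float, float, float] = (0.55, 0.15, 0.30)

    def all_ids(self) -> set[str]:
        return set(self.train_ids) | set(self.validation_ids) | set(self.test_ids)


def map_annotation(code: str, exclude_noisy: bool = False) -> str | None:
    """Map a challenge annotation code to the two-class label.

    ``A`` is AF; ``N`` (normal) and ``O`` (other rhythm) are non-AF. The
    noisy code ``~`` is folded into non-AF by default, since the three
    annotated rhythm groups exhaust the database; pass ``exclude_noisy=True``
    to drop those records instead (returns ``None``).
    """
    if code == "A":
        return AF
    if code in ("N", "O"):
        return NON_AF
    if code == "~":
        return None if exclude_noisy else NON_AF
    raise ValidationError(f"unknown annotation code {code!r}")


def compute_snr(samples: Sequence[float]) -> float:
    """Amplitude SNR in dB of a raw (unfiltered) recording.

    Signal amplitude is the maximum absolute sample; noise amplitude is four
    times the sample standard deviation::

        SNR_dB = 20 * log10( max|x| / (4 * sigma(x)) )
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least two samples for SNR")
    sigma = float(np.std(x, ddof=1))
    if sigma == 0.0:
        raise DegenerateSignalError("constant signal has undefined SNR")
    return float(20.0 * np.log10(np.max(np.abs(x)) / (4.0 * sigma)))


def accept_record(rpeaks: Sequence[int]) -> bool:
    """Acceptance gate: at least three consecutive R peaks were identified."""
    r = np.asarray(rpeaks)
    if r.size >= 2 and not np.all(np.diff(r) > 0):
        raise ValidationError("R-peak indices must be strictly increasing")
    return int(r.size) >= 3


def _apportion(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of ``n`` items over ``fractions``.

    Ties between equal remainders are broken in list order, i.e. the earlier
    split (train before validation before test) wins.
    """
    exact = [f * n for f in fractions]
    counts = [int(np.floor(e)) for e in exact]
    remainders = [e - c for e, c in zip(exact, counts)]
    short = n - sum(counts)
    # stable sort on -remainder keeps list order among ties
    order = sorted(range(len(fractions)), key=lambda i: -remainders[i])
    for i in order[:short]:
        counts[i] += 1
    return counts


def stratified_split(
    labels: Mapping[str, str],
    fractions: tuple[float, float, float] = (0.55, 0.15, 0.30),
    seed: int = 0,
) -> DatasetSplit:
    """Class-stratified train/validation/test split.

    Within each class, ids are sorted lexicographically (cross-platform
    determinism), shuffled with the seeded generator, and apportioned by
    floor + largest remainder so the per-class count in each split deviates
    from the exact fraction by at most one record.
    """
    if any(f < 0 for f in fractions):
        raise ValidationError("fractions must be non-negative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError("fractions must sum to 1")
    if not labels:
        raise ValidationError("empty label map")

    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for rid in sorted(labels):
        by_class.setdefault(labels[rid], []).append(rid)

    split: list[list[str]] = [[], [], []]
    for cls in sorted(by_class):
        ids = list(by_class[cls])
        rng.shuffle(ids)
        n_tr, n_va, n_te = _apportion(len(ids), fractions)
        split[0].extend(ids[:n_tr])
        split[1].extend(ids[n_tr : n_tr + n_va])
        split[2].extend(ids[n_tr + n_va :])
    return DatasetSplit(split[0], split[1], split[2], tuple(fractions))


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------


def _parse_wfdb_header(hea_path: Path) -> dict:
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ReadError(f"empty header {hea_path}")
    rec = lines[0].split()
    if len(rec) < 3:
        raise ReadError(f"malformed record line in {hea_path}")
    name = rec[0].split("/")[0]
    fs = float(rec[2]) if len(rec) > 2 else 250.0
    n_samples = int(rec[3]) if len(rec) > 3 else 0
    if len(lines) < 2:
        raise ReadError(f"no signal line in {hea_path}")
    sig = lines[1].split()
    filename = sig[0]
    fmt = sig[1]
    byte_offset = 0
    if "+" in fmt:
        fmt, off = fmt.split("+", 1)
        byte_offset = int(off)
    gain = 200.0
    baseline = 0.0
    units = "mV"
    if len(sig) > 2:
        g = sig[2]
        if "/" in g:
            g, units = g.split("/", 1)
        if "(" in g:
            g, b = g.split("(", 1)
            baseline = float(b.rstrip(")"))
        if g:
            gain = float(g)
    # WFDB: ADC zero (field 5) is the fallback baseline when none is given
    if "(" not in sig[2] and len(sig) > 4:
        baseline = float(sig[4])
    return {
        "name": name,
        "fs": fs,
        "n_samples": n_samples,
        "filename": filename,
        "format": fmt,
        "byte_offset": byte_offset,
        "gain": gain,
        "baseline": baseline,
        "units": units,
    }


def _read_wfdb_samples(sample_path: Path, header: dict) -> np.ndarray:
    if not sample_path.exists():
        raise ReadError(f"sample file not found: {sample_path}")
    if sample_path.suffix.lower() == ".mat":
        from scipy.io import loadmat

        try:
            mat = loadmat(str(sample_path))
        except Exception as exc:  # pragma: no cover - corrupt input
            raise ReadError(f"cannot read MAT file {sample_path}: {exc}") from exc
        key = "val" if "val" in mat else next(
            (k for k in mat if not k.startswith("__")), None
        )
        if key is None:
            raise ReadError(f"no data variable in {sample_path}")
        adc = np.asarray(mat[key], dtype=float).ravel()
    else:
        if header["format"] != "16":
            raise ReadError(f"unsupported WFDB format {header['format']!r}")
        raw = sample_path.read_bytes()[header["byte_offset"] :]
        adc = np.frombuffer(raw, dtype="<i2").astype(float)
    if adc.size == 0:
        raise ReadError(f"zero-length sample file {sample_path}")
    n = header["n_samples"]
    if n and adc.size >= n:
        adc = adc[:n]
    return adc


_UNIT_TO_UV = {"mV": 1000.0, "mv": 1000.0, "uV": 1.0, "uv": 1.0, "V": 1e6}


def read_record(
    path: str | Path,
    dialect: str = "wfdb2017",
    fs: float = 300.0,
    strict: bool = False,
    expected_fs: float = 300.0,
    annotation: str | None = None,
) -> ECGRecord:
    """Read one record; returns amplitudes in microvolts.

    ``path`` is the ``.hea`` file (or record stem) for the wfdb2017 dialect
    and the sample file itself for the csv dialect. ``strict`` rejects
    records whose header rate differs from ``expected_fs``.
    """
    path = Path(path)
    if dialect == "csv":
        if not path.exists():
            raise ReadError(f"file not found: {path}")
        try:
            samples = np.loadtxt(path, dtype=float, ndmin=1)
        except Exception as exc:
            raise ReadError(f"cannot parse CSV record {path}: {exc}") from exc
        if samples.size == 0:
            raise ReadError(f"zero-length record {path}")
        rate = fs
    elif dialect == "wfdb2017":
        hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
        if not hea.exists():
            raise ReadError(f"header not found: {hea}")
        header = _parse_wfdb_header(hea)
        rate = header["fs"]
        adc = _read_wfdb_samples(hea.parent / header["filename"], header)
        to_uv = _UNIT_TO_UV.get(header["units"], 1000.0)
        samples = (adc - header["baseline"]) / header["gain"] * to_uv
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")

    if strict and abs(rate - expected_fs) > 1e-9:
        raise ValidationError(
            f"record {path.stem}: fs {rate} differs from expected {expected_fs}"
        )
    label = map_annotation(annotation) if annotation is not None else None
    return ECGRecord(
        record_id=path.stem.replace(".hea", ""),
        fs=rate,
        samples=samples,
        label=label,
        raw_annotation=annotation,
    )


def read_reference(path: str | Path) -> dict[str, str]:
    """Read a headerless two-column ``REFERENCE.csv`` (id, annotation code)."""
    path = Path(path)
    if not path.exists():
        raise ReadError(f"reference file not found: {path}")
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            if len(row) < 2:
                raise ReadError(f"malformed reference row {row!r} in {path}")
            out[row[0].strip()] = row[1].strip()
    return out


def load_directory(
    directory: str | Path,
    dialect: str = "wfdb2017",
    fs: float = 300.0,
    exclude_noisy: bool = False,
) -> list[ECGRecord]:
    """Read every record listed in ``REFERENCE.csv`` under ``directory``."""
    directory = Path(directory)
    codes = read_reference(directory / "REFERENCE.csv")
    records = []
    for rid in sorted(codes):
        label = map_annotation(codes[rid], exclude_noisy=exclude_noisy)
        if label is None:
            continue
        ext = ".csv" if dialect == "csv" else ".hea"
        rec = read_record(
            directory / f"{rid}{ext}", dialect=dialect, fs=fs, annotation=codes[rid]
        )
        records.append(rec)
    return records
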