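"""End-to-end orchestration: features -> split -> RSL search -> evaluation.

The two estimators compose with scikit-learn:

* :class:`ECGFeatureExtractor` - a (stateless) transformer mapping a list
  of :class:`~fibrillens.io_dataset.ECGRecord` to the 19-column feature
  table (11 morphological, 4 F-wave, 4 HRV features);
* :class:`RSLANNClassifier` - the constructively grown sigmoid network.
  ``fit`` standardises features with training-set statistics, runs the
  multi-restart RSL search against an explicit (or internally split)
  validation set, and exposes the fitted network as ``model_``.

:func:`run_experiment` reproduces the full study protocol on a record
directory or a synthetic dataset: SNR characterisation, acceptance gate,
feature extraction, 55/15/30 stratified split, RSL training on the
train+validation data only, and ROC/AUC evaluation with the two clinical
operating points on the untouched test split.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from . import beat_morphology as bm
from . import fwaves, hrv, preprocess, rsl_ann
from .errors import FibrillensError, ValidationError
from .evaluation import feature_summary, operating_point, roc_curve
from .io_dataset import (
    AF,
    DatasetSplit,
    ECGRecord,
    accept_record,
    compute_snr,
    load_directory,
    stratified_split,
)
from .rsl_ann import Architecture, NetworkModel, TrainConfig
from .synthetic import make_dataset

#: feature-table column spellings and units
FEATURE_NAMES: tuple[str, ...] = (
    "PpRp",
    "PpQRSoff",
    "QRSonQRSoff",
    "QRSonToff",
    "QRSoffToff",
    "AP",
    "AQRSon",
    "AQRS",
    "AQRSoff",
    "AT",
    "AQRS/AP",
    "FWFR_FFT",
    "FWFR_WLC",
    "FWFR_YWK",
    "FWFR_THM",
    "MRR",
    "SDRR",
    "RMSRR",
    "PRR50",
)

FEATURE_UNITS: dict[str, str] = {
    **{n: "ms" for n in ("PpRp", "PpQRSoff", "QRSonQRSoff", "QRSonToff", "QRSoffToff")},
    **{n: "uV" for n in ("AP", "AQRSon", "AQRS", "AQRSoff", "AT")},
    "AQRS/AP": "dimensionless",
    **{n: "%" for n in ("FWFR_FFT", "FWFR_WLC", "FWFR_YWK", "FWFR_THM")},
    **{n: "ms" for n in ("MRR", "SDRR", "RMSRR")},
    "PRR50": "%",
}


@dataclass
class FeatureConfig:
    """Signal-processing settings shared by every extraction."""

    filter_order: int = 6
    filter_low_hz: float = 0.5
    filter_high_hz: float = 45.0
    rpeak_refractory_ms: float = 200.0
    rpeak_refine_ms: float = 40.0
    sbmm_t_pre_ms: float = 100.0
    sbmm_t_qrs_ms: float = 140.0
    fwfr_total_band: tuple[float, float] | None = None  # None = up to Nyquist
    prr50_mode: str = "as-written"
    rmsrr_mode: str = "successive"
    baseline_mode: str = "point"


def extract_features(
    record: ECGRecord, config: FeatureConfig | None = None
) -> tuple[dict[str, float], dict[str, str]]:
    """All 19 features of one accepted record, with per-group status flags.

    Returns ``(values, status)``; a group that fails leaves NaN in its
    features and the error message in its status entry. FWFR fractions are
    reported in percent, matching the feature-table units.
    """
    cfg = config or FeatureConfig()
    values: dict[str, float] = {n: np.nan for n in FEATURE_NAMES}
    status: dict[str, str] = {"morphology": "ok", "fwaves": "ok", "hrv": "ok"}

    xf = preprocess.bandpass_filter(
        record.samples,
        record.fs,
        low_hz=cfg.filter_low_hz,
        high_hz=cfg.filter_high_hz,
        order=cfg.filter_order,
    )
    rpeaks = preprocess.detect_rpeaks(
        xf,
        record.fs,
        refractory_ms=cfg.rpeak_refractory_ms,
        refine_ms=cfg.rpeak_refine_ms,
    )

    try:
        segments = bm.extract_beat_segments(xf, rpeaks, record.fs)
        mb = bm.median_beat(segments, record.fs)
        lm = bm.find_landmarks(mb)
        morph = bm.morphological_features(mb, lm, baseline_mode=cfg.baseline_mode)
        values.update(morph.to_dict())
    except FibrillensError as exc:
        status["morphology"] = f"{type(exc).__name__}: {exc}"

    try:
        dominant = fwaves.sbmm_dominant(
            xf, rpeaks, record.fs, t_pre_ms=cfg.sbmm_t_pre_ms, t_qrs_ms=cfg.sbmm_t_qrs_ms
        )
        res = fwaves.residual(xf, dominant)
        fw = fwaves.fwfr_features(res, record.fs, total_band=cfg.fwfr_total_band)
        values.update({k: 100.0 * v for k, v in fw._asdict().items()})
    except FibrillensError as exc:
        status["fwaves"] = f"{type(exc).__name__}: {exc}"

    try:
        rr = hrv.rr_series(rpeaks)
        hv = hrv.hrv_features(rr, prr50_mode=cfg.prr50_mode, rmsrr_mode=cfg.rmsrr_mode)
        values.update(hv._asdict())
    except FibrillensError as exc:
        status["hrv"] = f"{type(exc).__name__}: {exc}"

    return values, status


class ECGFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer from ECG records to the 19-feature table.

    Stateless (``fit`` only records the feature names); ``transform``
    accepts a sequence of :class:`ECGRecord` and returns a DataFrame
    indexed by record id. Records failing a stage carry NaN in that
    stage's features; the per-record status of the last transform is kept
    in ``status_``.
    """

    def __init__(self, config: FeatureConfig | None = None):
        self.config = config

    def fit(self, X: Sequence[ECGRecord], y=None) -> "ECGFeatureExtractor":
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def transform(self, X: Sequence[ECGRecord]) -> pd.DataFrame:
        rows, status = {}, {}
        for rec in X:
            values, st = extract_features(rec, self.config)
            rows[rec.record_id] = values
            status[rec.record_id] = st
        self.status_ = status
        return pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)


class RSLANNClassifier(ClassifierMixin, BaseEstimator):
    """Sigmoid MLP grown by repeated structuring and learning.

    Parameters mirror :class:`~fibrillens.rsl_ann.TrainConfig` plus the
    restart count. ``fit`` z-scores the inputs with training-set statistics
    (the raw features span four orders of magnitude, which would defeat the
    uniform [-1, 1] initialisation), splits off an internal stratified
    validation set unless one is passed explicitly, and runs the
    multi-restart search.

    Attributes set by ``fit``: ``model_`` (network), ``architecture_``,
    ``validation_loss_``, ``search_logs_``, ``mean_``, ``scale_``,
    ``classes_``.
    """

    def __init__(
        self,
        n_restarts: int = 5,
        validation_fraction: float = 0.2,
        max_epochs: int = 1000,
        patience: int = 6,
        loss: str = "cross_entropy",
        screen_trials: int = 10,
        confirm_limit: int = 10,
        max_rounds: int = 25,
        random_state: int = 0,
    ):
        self.n_restarts = n_restarts
        self.validation_fraction = validation_fraction
        self.max_epochs = max_epochs
        self.patience = patience
        self.loss = loss
        self.screen_trials = screen_trials
        self.confirm_limit = confirm_limit
        self.max_rounds = max_rounds
        self.random_state = random_state

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            max_epochs=self.max_epochs,
            patience=self.patience,
            loss=self.loss,
            screen_trials=self.screen_trials,
            confirm_limit=self.confirm_limit,
            max_rounds=self.max_rounds,
        )

    def fit(self, X, y, X_val=None, y_val=None) -> "RSLANNClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValidationError("X must be 2-D and aligned with y")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValidationError("binary classification only")
        y01 = (y == self.classes_[1]).astype(float)

        if X_val is None:
            X_tr, X_va, y_tr, y_va = train_test_split(
                X,
                y01,
                test_size=self.validation_fraction,
                stratify=y01,
                random_state=self.random_state,
            )
        else:
            X_tr, y_tr = X, y01
            X_va = np.asarray(X_val, dtype=float)
            y_va = (np.asarray(y_val) == self.classes_[1]).astype(float)

        self.mean_ = X_tr.mean(axis=0)
        scale = X_tr.std(axis=0)
        self.scale_ = np.where(scale > 0, scale, 1.0)
        Z_tr = (X_tr - self.mean_) / self.scale_
        Z_va = (X_va - self.mean_) / self.scale_

        self.model_, self.search_logs_ = rsl_ann.multi_restart(
            (Z_tr, y_tr),
            (Z_va, y_va),
            self._train_config(),
            n_restarts=self.n_restarts,
            seed=self.random_state,
            n_inputs=X.shape[1],
        )
        self.architecture_ = self.model_.architecture
        self.validation_loss_ = min(
            log.final_validation_loss for log in self.search_logs_
        )
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        return np.asarray(rsl_ann.forward(self.model_, Z))

    def predict_proba(self, X) -> np.ndarray:
        p = self.decision_function(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        p = self.decision_function(X)
        return np.where(p >= 0.5, self.classes_[1], self.classes_[0])


# ---------------------------------------------------------------------------
# model serialisation
# ---------------------------------------------------------------------------

_MODEL_FORMAT = 1


def save_model(clf: RSLANNClassifier, path: str | Path) -> None:
    """Versioned JSON serialisation of a fitted classifier."""
    check_is_fitted(clf, "model_")
    m = clf.model_
    payload = {
        "format": _MODEL_FORMAT,
        "architecture": list(m.architecture.hidden_sizes),
        "n_inputs": m.n_inputs,
        "weights": [w.tolist() for w in m.weights],
        "biases": [b.tolist() for b in m.biases],
        "mean": clf.mean_.tolist(),
        "scale": clf.scale_.tolist(),
        "classes": [str(c) for c in clf.classes_],
        "random_state": clf.random_state,
        "params_hash": hashlib.sha256(
            json.dumps(clf.get_params(), sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> RSLANNClassifier:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != _MODEL_FORMAT:
        raise ValidationError(f"unsupported model format {payload.get('format')!r}")
    clf = RSLANNClassifier(random_state=payload["random_state"])
    arch = Architecture(tuple(payload["architecture"]))
    clf.model_ = NetworkModel(
        arch,
        [np.asarray(w, dtype=float) for w in payload["weights"]],
        [np.asarray(b, dtype=float) for b in payload["biases"]],
        payload["n_inputs"],
    )
    clf.architecture_ = arch
    clf.mean_ = np.asarray(payload["mean"], dtype=float)
    clf.scale_ = np.asarray(payload["scale"], dtype=float)
    clf.classes_ = np.asarray(payload["classes"])
    clf.n_features_in_ = payload["n_inputs"]
    return clf


# ---------------------------------------------------------------------------
# the experiment protocol
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything one experiment needs; serialisable and hashable."""

    data_dir: str | None = None  # None -> synthesize
    dialect: str = "csv"
    fs: float = 300.0
    n_af: int = 150
    n_nonaf: int = 150
    synth_seed: int = 0
    fractions: tuple[float, float, float] = (0.55, 0.15, 0.30)
    split_seed: int = 0
    n_restarts: int = 5
    model_seed: int = 0
    sp_floor: float = 0.75
    out_dir: str | None = None
    features: FeatureConfig = field(default_factory=FeatureConfig)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _gate(records: Sequence[ECGRecord], cfg: RunConfig):
    """SNR characterisation plus the three-R-peak acceptance gate."""
    accepted, rejected, snr = [], [], {}
    for rec in records:
        snr[rec.record_id] = compute_snr(rec.samples)
        try:
            xf = preprocess.bandpass_filter(
                rec.samples,
                rec.fs,
                low_hz=cfg.features.filter_low_hz,
                high_hz=cfg.features.filter_high_hz,
                order=cfg.features.filter_order,
            )
            rpeaks = preprocess.detect_rpeaks(xf, rec.fs)
            ok = accept_record(rpeaks.indices)
        except FibrillensError:
            ok = False
        (accepted if ok else rejected).append(rec)
    return accepted, rejected, snr


def run_experiment(config: RunConfig) -> dict:
    """Run the full protocol; returns the report bundle as a dict.

    Artifacts (feature table CSV with a units header row, model JSON,
    report JSON/Markdown) are written when ``config.out_dir`` is set. Test
    records influence nothing but the final evaluation.
    """
    if config.data_dir is not None:
        records = load_directory(config.data_dir, dialect=config.dialect, fs=config.fs)
    else:
        records = [rec for rec, _ in make_dataset(
            config.n_af, config.n_nonaf, seed=config.synth_seed
        )]
    if not records:
        raise ValidationError("no records to process")

    accepted, rejected, snr = _gate(records, config)
    extractor = ECGFeatureExtractor(config.features).fit(accepted)
    table = extractor.transform(accepted)
    labels = pd.Series({r.record_id: r.label for r in accepted})

    complete = table.dropna().index
    excluded = sorted(set(table.index) - set(complete))
    table_ok = table.loc[complete]
    labels_ok = labels.loc[complete]

    split = stratified_split(
        labels_ok.to_dict(), fractions=config.fractions, seed=config.split_seed
    )

    def xy(ids):
        return table_ok.loc[ids].to_numpy(), labels_ok.loc[ids].to_numpy()

    X_tr, y_tr = xy(split.train_ids)
    X_va, y_va = xy(split.validation_ids)
    X_te, y_te = xy(split.test_ids)

    clf = RSLANNClassifier(
        n_restarts=config.n_restarts, random_state=config.model_seed
    ).fit(X_tr, y_tr, X_val=X_va, y_val=y_va)

    report: dict = {
        "config_hash": config.config_hash(),
        "n_records": len(records),
        "n_accepted": len(accepted),
        "n_rejected": len(rejected),
        "n_excluded_extraction": len(excluded),
        "snr_db_median_accepted": float(
            np.median([snr[r.record_id] for r in accepted])
        ) if accepted else np.nan,
        "architecture": list(clf.architecture_.hidden_sizes),
        "validation_loss": clf.validation_loss_,
        "splits": {},
    }

    af_col = list(clf.classes_).index(AF)
    scores = {}
    for name, (X, y) in {
        "training": (X_tr, y_tr),
        "validation": (X_va, y_va),
        "testing": (X_te, y_te),
    }.items():
        s = clf.predict_proba(X)[:, af_col]
        scores[name] = (s, y)
        curve = roc_curve(s, (y == AF).astype(int))
        report["splits"][name] = {
            "n": int(len(y)),
            "n_af": int(np.sum(y == AF)),
            "auc": curve.auc,
            "ci95": list(curve.ci95),
        }

    s_te, y_te_ = scores["testing"]
    curve_te = roc_curve(s_te, (y_te_ == AF).astype(int))
    for case in (1, 2):
        op = operating_point(curve_te, case, sp_floor=config.sp_floor)
        report[f"case{case}"] = {
            "threshold": op.threshold,
            "se": op.se,
            "sp": op.sp,
            "feasible": op.feasible,
        }
    report["roc_testing"] = {
        "thresholds": curve_te.thresholds.tolist(),
        "se": curve_te.se.tolist(),
        "sp": curve_te.sp.tolist(),
    }

    summary = feature_summary(table_ok, labels_ok)
    report["feature_summary"] = summary.reset_index().to_dict(orient="records")
    report["n_significant_features"] = int(summary["significant"].sum())

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        units = pd.DataFrame(
            [[FEATURE_UNITS[c] for c in table.columns]], columns=table.columns,
            index=["unit"],
        )
        pd.concat([units, table]).to_csv(out / "features.csv", index_label="record_id")
        save_model(clf, out / "model.json")
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        (out / "report.md").write_text(_markdown_report(report))

    report["_classifier"] = clf
    report["_scores"] = scores
    report["_split"] = split
    report["_features"] = table_ok
    report["_labels"] = labels_ok
    return report


def _markdown_report(report: dict) -> str:
    lines = ["# AF identification report", ""]
    lines.append(
        f"Records: {report['n_records']} ({report['n_accepted']} accepted, "
        f"{report['n_rejected']} rejected by the R-peak gate, "
        f"{report['n_excluded_extraction']} excluded at feature extraction)"
    )
    lines.append(f"Final architecture: {report['architecture']}")
    lines.append("")
    lines.append("| dataset | n | AF | AUC | 95% CI |")
    lines.append("|---|---|---|---|---|")
    for name, d in report["splits"].items():
        lines.append(
            f"| {name} | {d['n']} | {d['n_af']} | {d['auc']*100:.1f}% | "
            f"{d['ci95'][0]*100:.1f}-{d['ci95'][1]*100:.1f}% |"
        )
    lines.append("")
    for case in (1, 2):
        d = report[f"case{case}"]
        lines.append(
            f"Case {case}: Se {d['se']*100:.1f}%, Sp {d['sp']*100:.1f}% "
            f"(threshold {d['threshold']:.3f})"
        )
    return "\n".join(lines) + "\n"
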