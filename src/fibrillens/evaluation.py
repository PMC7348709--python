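"""ROC analysis, operating points, and class-wise feature statistics.

Sensitivity (Se) is the detection rate over the AF class, specificity (Sp)
the rejection rate over non-AF. Two clinically motivated operating points
are read off the ROC curve: Case 1 picks the threshold where Se equals Sp
(screening subjects with no AF history, where both error types weigh the
same); Case 2 maximises Se subject to Sp >= 75% (subjects with known AF
history, where missing AF is the costlier error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # descending cutoffs (predict AF when score >= t)
    se: np.ndarray
    sp: np.ndarray
    auc: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int


@dataclass
class OperatingPoint:
    threshold: float
    se: float
    sp: float
    case: int
    feasible: bool = True


def _check_binary(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.size != y.size or s.size == 0:
        raise ValidationError("scores and labels must be non-empty and aligned")
    if set(np.unique(y)) != {0, 1}:
        raise ValidationError("both classes must be present")
    return s, y


def roc_curve(scores, labels, ci_method: str = "hanley-mcneil") -> ROCCurve:
    """ROC curve over all unique score thresholds, AUC by trapezoid.

    ``labels``: 1 = AF (positive), 0 = non-AF.
    """
    s, y = _check_binary(scores, labels)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    # cumulative counts: predict positive when score >= threshold
    se = np.array([np.sum((s >= t) & (y == 1)) / n_pos for t in thresholds])
    sp = np.array([np.sum((s < t) & (y == 0)) / n_neg for t in thresholds])
    auc = float(np.trapezoid(se, 1.0 - sp))
    curve = ROCCurve(thresholds, se, sp, auc, (np.nan, np.nan), n_pos, n_neg)
    curve.ci95 = auc_ci(s, y, method=ci_method)
    return curve


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def _delong_se(s: np.ndarray, y: np.ndarray) -> float:
    pos = s[y == 1]
    neg = s[y == 0]
    # placement values
    v_pos = np.array([np.mean((x > neg) + 0.5 * (x == neg)) for x in pos])
    v_neg = np.array([np.mean((pos > x) + 0.5 * (pos == x)) for x in neg])
    var = np.var(v_pos, ddof=1) / pos.size + np.var(v_neg, ddof=1) / neg.size
    return float(np.sqrt(max(var, 0.0)))


def auc_ci(scores, labels, method: str = "hanley-mcneil") -> tuple[float, float]:
    """95% confidence interval of the AUC, clipped to [0, 1]."""
    s, y = _check_binary(scores, labels)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    pos, neg = s[y == 1], s[y == 0]
    # tie-aware Mann-Whitney AUC (equals the trapezoidal ROC area)
    auc = float(
        (np.sum(pos[:, None] > neg[None, :]) + 0.5 * np.sum(pos[:, None] == neg[None, :]))
        / (n_pos * n_neg)
    )
    if method == "hanley-mcneil":
        se = _hanley_mcneil_se(auc, n_pos, n_neg)
    elif method == "delong":
        se = _delong_se(s, y)
    else:
        raise ValidationError(f"unknown CI method {method!r}")
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    return (lo, hi)


def operating_point(curve: ROCCurve, case: int, sp_floor: float = 0.75) -> OperatingPoint:
    """Clinical operating point on a fitted ROC curve.

    Case 1: threshold minimising |Se - Sp| (ties resolved toward higher
    Se). Case 2: maximal Se among thresholds with Sp >= ``sp_floor``; if no
    threshold is feasible the point at maximal available Sp is returned
    with ``feasible=False``.
    """
    se, sp, thr = curve.se, curve.sp, curve.thresholds
    if case == 1:
        gap = np.abs(se - sp)
        best_gap = gap.min()
        ties = np.flatnonzero(gap == best_gap)
        i = ties[np.argmax(se[ties])]
        return OperatingPoint(float(thr[i]), float(se[i]), float(sp[i]), 1)
    if case == 2:
        feasible = np.flatnonzero(sp >= sp_floor)
        if feasible.size == 0:
            i = int(np.argmax(sp))
            return OperatingPoint(float(thr[i]), float(se[i]), float(sp[i]), 2, False)
        best_se = se[feasible].max()
        ties = feasible[se[feasible] == best_se]
        i = ties[np.argmax(sp[ties])]
        return OperatingPoint(float(thr[i]), float(se[i]), float(sp[i]), 2)
    raise ValidationError(f"case must be 1 or 2, got {case}")


def ranksum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution for small tie-free samples (n <= 10 per group),
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def feature_summary(
    features: pd.DataFrame,
    labels,
    positive: str = "AF",
    negative: str = "nonAF",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature 50th [25th; 75th] percentiles by class plus rank-sum p.

    ``features`` has one row per record and one column per feature;
    ``labels`` aligns with its index. Percentiles interpolate linearly
    between order statistics; rows are marked significant at p < alpha.
    NaN entries (failed extractions) are dropped per feature.
    """
    y = pd.Series(np.asarray(labels), index=features.index)
    if (y == positive).sum() < 1 or (y == negative).sum() < 1:
        raise ValidationError("need at least one record per class")
    rows = []
    for name in features.columns:
        af_vals = features.loc[y == positive, name].dropna().to_numpy()
        non_vals = features.loc[y == negative, name].dropna().to_numpy()
        q_af = np.percentile(af_vals, [50, 25, 75]) if af_vals.size else [np.nan] * 3
        q_non = np.percentile(non_vals, [50, 25, 75]) if non_vals.size else [np.nan] * 3
        p = (
            ranksum_test(af_vals, non_vals)
            if af_vals.size and non_vals.size
            else np.nan
        )
        rows.append(
            {
                "feature": name,
                "af_median": q_af[0],
                "af_q25": q_af[1],
                "af_q75": q_af[2],
                "nonaf_median": q_non[0],
                "nonaf_q25": q_non[1],
                "nonaf_q75": q_non[2],
                "p_value": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
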