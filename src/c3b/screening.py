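"""Impairment classification and signal-detection diagnostics.

A subject is screened on the pair of adjusted z-scores (PST, VMT).  The
impairment rule is the minimum of the two: a subject is called impaired
when ``min(z_pst, z_vmt)`` falls strictly below the cutoff (default
z < -0.4), because an MCI patient may be deficient in episodic memory,
processing speed, or both.  Group discrimination is quantified with a
confusion matrix (sensitivity, specificity, Youden's J), the empirical ROC
curve and its AUC, the Youden-optimal cutoff, and independent-groups
effect sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "DEFAULT_CUTOFF",
    "DegenerateDataError",
    "UndefinedMetricError",
    "ScreeningRecord",
    "ConfusionMatrix",
    "ROCCurve",
    "classify",
    "confusion",
    "diagnostics",
    "roc",
    "youden_optimal_cutoff",
    "youden_optimal_z_cutoff",
    "independent_groups_summary",
]

DEFAULT_CUTOFF = -0.4


class DegenerateDataError(ValueError):
    """Input data carry no variance where variance is required."""


class UndefinedMetricError(ValueError):
    """A diagnostic metric is undefined because a truth class is empty."""


@dataclass(frozen=True)
class ScreeningRecord:
    """One subject's z-pair, impairment call and (optional) diagnosis."""

    subject_id: str
    z_pst: float | None
    z_vmt: float | None
    call: Literal["impaired", "WNL", "unscorable"]
    truth: Literal["MCI", "HC"] | None = None

    @property
    def min_z(self) -> float | None:
        zs = [z for z in (self.z_pst, self.z_vmt) if z is not None and not math.isnan(z)]
        return min(zs) if zs else None


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC: thresholds on the discriminant (larger = more
    impaired) with the matching (FPR, TPR) staircase and trapezoidal AUC."""

    thresholds: tuple[float, ...]
    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    auc: float


def classify(
    z_pst: float | None,
    z_vmt: float | None,
    cutoff: float = DEFAULT_CUTOFF,
) -> Literal["impaired", "WNL", "unscorable"]:
    """Impairment call from the min-z rule: impaired iff min z < cutoff.

    The inequality is strict, so a z exactly at the cutoff is WNL.  With
    one z missing the call is made on the available score; with both
    missing the record is unscorable.
    """
    zs = [z for z in (z_pst, z_vmt) if z is not None and not math.isnan(z)]
    if not zs:
        return "unscorable"
    return "impaired" if min(zs) < cutoff else "WNL"


def confusion(records: Sequence[ScreeningRecord]) -> ConfusionMatrix:
    """Cross-tabulate impairment calls against MCI/HC diagnoses.

    Unscorable records are excluded; records without a truth label raise.
    """
    missing = [r.subject_id for r in records if r.call != "unscorable" and r.truth is None]
    if missing:
        raise ValueError(f"records missing truth labels: {', '.join(missing)}")
    tp = fp = tn = fn = 0
    for r in records:
        if r.call == "unscorable":
            continue
        impaired = r.call == "impaired"
        if r.truth == "MCI":
            tp += impaired
            fn += not impaired
        else:
            fp += impaired
            tn += not impaired
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def diagnostics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(sensitivity, specificity, Youden's J) from a confusion matrix."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("no positive-truth (MCI) subjects: sensitivity undefined")
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("no negative-truth (HC) subjects: specificity undefined")
    sens = cm.tp / (cm.tp + cm.fn)
    spec = cm.tn / (cm.tn + cm.fp)
    return sens, spec, sens + spec - 1.0


def _split_scores(scores, truth) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(truth)
    if labels.dtype.kind == "b":
        mask = labels
    else:
        mask = labels.astype(str) == "MCI"
    pos, neg = scores[mask], scores[~mask]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedMetricError("ROC requires both MCI and HC subjects")
    return pos, neg


def roc(scores: Sequence[float], truth: Sequence) -> ROCCurve:
    """Empirical ROC curve and trapezoidal AUC.

    ``scores`` is the discriminant with larger = more impaired (use
    ``-min_z``); ``truth`` is "MCI"/"HC" labels or booleans (True = case).
    The trapezoidal AUC equals P(case > control) + 0.5 P(tie) over all
    case-control pairs.
    """
    pos, neg = _split_scores(scores, truth)
    y = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    s = np.concatenate([pos, neg])
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=tuple(thr), fpr=tuple(fpr), tpr=tuple(tpr), auc=auc)


def youden_optimal_cutoff(
    scores: Sequence[float], truth: Sequence
) -> tuple[float, float]:
    """Threshold on the discriminant maximizing Youden's J.

    Candidates are midpoints between adjacent distinct observed scores
    plus the two open ends; a subject is called positive iff
    score > threshold.  Ties in J are broken toward the higher threshold
    (fewer positives, higher specificity).
    """
    pos, neg = _split_scores(scores, truth)
    uniq = np.unique(np.concatenate([pos, neg]))
    mids = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else np.array([])
    candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    best_thr = best_j = -np.inf
    for thr in candidates:
        sens = float(np.mean(pos > thr))
        spec = float(np.mean(neg <= thr))
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and thr > best_thr):
            best_j, best_thr = j, float(thr)
    return best_thr, best_j


def youden_optimal_z_cutoff(
    z_min: Sequence[float], truth: Sequence
) -> tuple[float, float]:
    """Youden-optimal cutoff expressed on the z scale (impaired iff
    min z < cutoff), via the -z discriminant."""
    thr, j = youden_optimal_cutoff(-np.asarray(z_min, dtype=float), truth)
    return -thr, j


def independent_groups_summary(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = False,
) -> dict[str, float]:
    """Two-sample comparison: means/SDs, t, two-sided p, Cohen's d.

    The t statistic is Student's pooled-variance t for ``group_b - group_a``
    (Welch's correction behind the ``welch`` flag) and
    ``d = (mean_b - mean_a) / pooled SD`` with (n-1) weights, so with
    ``group_a`` = patients and ``group_b`` = controls a positive d means
    patients score lower.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    sa, sb = a.std(ddof=1), b.std(ddof=1)
    pooled_var = ((len(a) - 1) * sa**2 + (len(b) - 1) * sb**2) / (len(a) + len(b) - 2)
    if pooled_var == 0:
        raise DegenerateDataError("zero pooled variance")
    t, p = stats.ttest_ind(b, a, equal_var=not welch)
    return {
        "mean_a": float(a.mean()),
        "sd_a": float(sa),
        "n_a": len(a),
        "mean_b": float(b.mean()),
        "sd_b": float(sb),
        "n_b": len(b),
        "t": float(t),
        "p": float(p),
        "cohens_d": float((b.mean() - a.mean()) / np.sqrt(pooled_var)),
    }
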