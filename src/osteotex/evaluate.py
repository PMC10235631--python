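"""Confusion-matrix metrics, ROC/AUC, and percentile bootstrap CIs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve

from osteotex.errors import DataError, LabelError, UnstableCIError


@dataclass
class MetricSet:
    """Point metrics from one confusion matrix.

    Metrics with an undefined denominator are reported as 0.0 with their
    name listed in ``undefined``.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    sn: float
    sp: float
    precision: float
    f1: float
    mcc: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "acc": self.acc, "sn": self.sn, "sp": self.sp,
            "precision": self.precision, "f1": self.f1, "mcc": self.mcc,
        }


@dataclass
class EvalReport:
    """Full evaluation of one classifier on one labeled test set."""

    metrics: MetricSet
    auc: float
    roc_fpr: np.ndarray = field(repr=False, default=None)
    roc_tpr: np.ndarray = field(repr=False, default=None)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n: int = 0


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> MetricSet:
    """Sensitivity, specificity, accuracy, precision, F1 and MCC.

    The positive class is the disease class, so Sn is disease recall.
    """
    counts = (tp, fp, tn, fn)
    if any(c < 0 or int(c) != c for c in counts):
        raise DataError("counts must be nonnegative integers")
    tp, fp, tn, fn = (int(c) for c in counts)
    n = tp + fp + tn + fn
    if n == 0:
        raise DataError("empty evaluation: all counts are zero")
    undefined = []

    def _ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = (tp + tn) / n
    sn = _ratio(tp, tp + fn, "sn")
    sp = _ratio(tn, tn + fp, "sp")
    precision = _ratio(tp, tp + fp, "precision")
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "f1")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        undefined.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return MetricSet(
        tp=tp, fp=fp, tn=tn, fn=fn,
        acc=acc, sn=sn, sp=sp, precision=precision, f1=f1, mcc=float(mcc),
        undefined=tuple(undefined),
    )


def roc_auc(scores, labels) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """ROC curve (threshold sweep) and trapezoidal AUC.

    Tied scores get half credit, matching the rank-statistic (Mann-Whitney)
    form of the AUC.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if np.unique(labels).size != 2:
        raise LabelError("need both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return (fpr, tpr), auc


def bootstrap_ci(
    metric,
    scores,
    labels,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    max_redraw: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap CI of ``metric(scores, labels)``.

    Rows are resampled with replacement; resamples missing a class are
    redrawn (the count is tracked internally).  Raises if the metric is
    undefined (non-finite) on more than half of the resamples.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n = scores.shape[0]
    if n < 5:
        raise DataError("need at least 5 paired observations")
    rng = np.random.default_rng(seed)
    values = np.empty(n_boot)
    bad = 0
    for b in range(n_boot):
        for _ in range(max_redraw):
            idx = rng.integers(0, n, size=n)
            if np.unique(labels[idx]).size >= 2:
                break
        else:
            raise UnstableCIError("could not draw a two-class resample")
        try:
            v = float(metric(scores[idx], labels[idx]))
        except Exception:
            v = np.nan
        if not np.isfinite(v):
            bad += 1
            v = np.nan
        values[b] = v
    if bad > n_boot / 2:
        raise UnstableCIError(f"metric undefined on {bad}/{n_boot} resamples")
    good = values[np.isfinite(values)]
    lo = float(np.percentile(good, 100 * alpha / 2))
    hi = float(np.percentile(good, 100 * (1 - alpha / 2)))
    return lo, hi


def _metric_from_predictions(name: str):
    def metric(scores: np.ndarray, labels: np.ndarray) -> float:
        pred = scores >= 0
        pos = labels == 1
        tp = int(np.sum(pred & pos))
        fp = int(np.sum(pred & ~pos))
        tn = int(np.sum(~pred & ~pos))
        fn = int(np.sum(~pred & pos))
        return getattr(confusion_metrics(tp, fp, tn, fn), name)

    return metric


def evaluate_scores(
    scores,
    labels,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> EvalReport:
    """EvalReport (point metrics + AUC + bootstrap CIs) from signed scores.

    Labels must be 0/1 with 1 the disease (positive) class; predictions
    threshold the scores at zero.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pred = scores >= 0
    pos = labels == 1
    metrics = confusion_metrics(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )
    (fpr, tpr), auc = roc_auc(scores, labels)
    ci = {}
    for name in ("acc", "sn", "sp", "precision", "f1", "mcc"):
        ci[name] = bootstrap_ci(
            _metric_from_predictions(name), scores, labels, n_boot=n_boot, alpha=alpha, seed=seed
        )
    ci["auc"] = bootstrap_ci(
        lambda s, l: roc_auc(s, l)[1], scores, labels, n_boot=n_boot, alpha=alpha, seed=seed
    )
    return EvalReport(
        metrics=metrics, auc=auc, roc_fpr=fpr, roc_tpr=tpr, ci=ci, n=len(labels)
    )
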