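"""Classifier evaluation: ROC/AUC, confusion-matrix metrics with exact
binomial confidence intervals, and per-stratum sensitivity reporting.

AUC is the Mann-Whitney rank statistic (probability that a random cancer
sample outscores a random healthy one, ties counted 1/2); the assembled
ROC curve's trapezoidal area agrees with it exactly. Confidence intervals
are exact (Clopper-Pearson) by default, Wilson optionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RocCurve",
    "MetricsReport",
    "roc_auc",
    "confusion_metrics",
    "stratified_report",
    "binomial_ci",
    "percentage",
]


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    fpr: np.ndarray  # 1 - specificity
    auc: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "sensitivity": self.sensitivity, "fpr": self.fpr}
        )


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    metrics: dict  # name -> (estimate or None, ci_low, ci_high) ; CI None when undefined

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __getitem__(self, name: str):
        return self.metrics[name]

    def as_frame(self) -> pd.DataFrame:
        rows = [
            (k, v[0], v[1], v[2]) for k, v in self.metrics.items()
        ]
        return pd.DataFrame(rows, columns=["metric", "estimate", "ci_low", "ci_high"])


def binomial_ci(k: int, n: int, conf: float = 0.95, method: str = "clopper-pearson"):
    """Exact (Clopper-Pearson) or Wilson interval for a binomial proportion."""
    if n == 0:
        return (float("nan"), float("nan"))
    alpha = 1.0 - conf
    if method == "clopper-pearson":
        low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
        high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
        return (low, high)
    if method == "wilson":
        z = stats.norm.ppf(1 - alpha / 2)
        p = k / n
        denom = 1 + z**2 / n
        center = (p + z**2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        return (max(0.0, center - half), min(1.0, center + half))
    raise ValueError(f"unknown CI method {method!r}")


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve and rank-statistic AUC.

    ``labels`` is boolean/0-1 with 1 = cancer (positive). The AUC is the
    fraction of (cancer, healthy) pairs where the cancer score is higher,
    with ties contributing 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required for ROC analysis")
    # Mann-Whitney via midranks: U / (n_pos * n_neg)
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - len(pos) * (len(pos) + 1) / 2
    auc = float(u / (len(pos) * len(neg)))
    from sklearn.metrics import roc_curve as _sk_roc

    fpr, tpr, thr = _sk_roc(labels.astype(int), scores, drop_intermediate=False)
    # sklearn returns thresholds descending; reorder ascending so
    # sensitivity is non-increasing as the threshold rises
    order = np.argsort(thr)
    return RocCurve(
        thresholds=thr[order], sensitivity=tpr[order], fpr=fpr[order], auc=auc
    )


def _prop(name: str, k: int, n: int, conf: float, method: str, out: dict) -> None:
    if n == 0:
        out[name] = (None, None, None)  # undefined, CI omitted
        return
    low, high = binomial_ci(k, n, conf=conf, method=method)
    out[name] = (k / n, low, high)


def confusion_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    cutoff: float,
    conf: float = 0.95,
    ci_method: str = "clopper-pearson",
) -> MetricsReport:
    """Confusion counts at ``score >= cutoff => predicted cancer`` and the
    five standard proportions, each with an exact binomial CI:

    sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP),
    NPV TN/(TN+FN), accuracy (TP+TN)/total. Zero-denominator metrics are
    reported as undefined (None) with the CI omitted.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pred = scores >= cutoff
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    tn = int((~pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    out: dict = {}
    _prop("sensitivity", tp, tp + fn, conf, ci_method, out)
    _prop("specificity", tn, tn + fp, conf, ci_method, out)
    _prop("ppv", tp, tp + fp, conf, ci_method, out)
    _prop("npv", tn, tn + fn, conf, ci_method, out)
    _prop("accuracy", tp + tn, tp + fp + tn + fn, conf, ci_method, out)
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, metrics=out)


def stratified_report(
    scores: np.ndarray,
    labels: np.ndarray,
    strata: list[str],
    cutoff: float,
    conf: float = 0.95,
) -> pd.DataFrame:
    """Per-stratum sensitivity among true positives of each stratum.

    Unknown/missing stratum values are grouped as "Unknown"; empty strata
    are omitted; strata with fewer than 5 positives are flagged.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    strata = ["Unknown" if s in (None, "", "nan") else str(s) for s in strata]
    rows = []
    for stratum in sorted(set(strata)):
        in_s = np.array([s == stratum for s in strata]) & labels
        n = int(in_s.sum())
        if n == 0:
            continue
        detected = int((scores[in_s] >= cutoff).sum())
        low, high = binomial_ci(detected, n, conf=conf)
        rows.append((stratum, n, detected, detected / n, low, high, n < 5))
    return pd.DataFrame(
        rows,
        columns=["stratum", "n", "detected", "sensitivity", "ci_low", "ci_high", "small_stratum"],
    )


def percentage(k: int, n: int, ndigits: int = 1) -> float:
    """Share of a count in a total, as a percentage rounded for reporting
    (e.g. 50 of 119 -> 42.0)."""
    if n == 0:
        raise ValueError("total must be positive")
    return round(100.0 * k / n, ndigits)
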