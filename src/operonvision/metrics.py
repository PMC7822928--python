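"""Evaluation metrics for gene-pair calls and full-operon predictions.

Rate metrics follow the standard confusion-matrix definitions:

    sensitivity = TP / (TP + FN)          (true positive rate, recall)
    precision   = TP / (TP + FP)
    specificity = TN / (TN + FP)          (true negative rate)
    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    F1          = 2 * sensitivity * precision / (sensitivity + precision)

ROC and precision-recall curves are computed by a threshold sweep over the
unique scores, with AUC by the trapezoid rule (equal scores are grouped, so
the ROC AUC equals the pairwise concordance probability).

Full-operon evaluation counts a known multi-gene operon as matched only when
some prediction has exactly the same ordered gene list — identical endpoints,
no extensions.  A prediction that merges two known operons matches neither.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .assembly import OperonPrediction
from .classifier import PairCall
from .dataset import OPERONIC
from .io import OperonRecord


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise MetricsError("confusion counts must be non-negative")
        if self.TP + self.FP + self.FN + self.TN == 0:
            raise MetricsError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class MetricsReport:
    sensitivity: float
    precision: float
    specificity: float
    accuracy: float
    mcc: float
    f1: float
    mcc_degenerate: bool = False
    roc_auc: Optional[float] = None
    pr_auc: Optional[float] = None
    per_genome: dict[str, "MetricsReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "f1": self.f1,
            "mcc_degenerate": self.mcc_degenerate,
        }
        if self.roc_auc is not None:
            out["roc_auc"] = self.roc_auc
        if self.pr_auc is not None:
            out["pr_auc"] = self.pr_auc
        if self.per_genome:
            out["per_genome"] = {g: r.to_dict() for g, r in self.per_genome.items()}
        return out


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Rate metrics from a confusion table.

    Precision with TP+FP = 0 is undefined and reported as NaN.  MCC with any
    zero denominator factor is reported as 0 and flagged.
    """
    tp, fp, fn, tn = c.TP, c.FP, c.FN, c.TN
    sens = tp / (tp + fn) if tp + fn else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / c.total
    den_factors = [tp + fp, tp + fn, tn + fp, tn + fn]
    degenerate = any(f == 0 for f in den_factors)
    if degenerate:
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(math.prod(den_factors))
    if math.isnan(sens) or math.isnan(prec) or sens + prec == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * sens * prec / (sens + prec)
    return MetricsReport(
        sensitivity=sens,
        precision=prec,
        specificity=spec,
        accuracy=acc,
        mcc=mcc,
        f1=f1,
        mcc_degenerate=degenerate,
    )


def confusion_from_rates(
    sensitivity: float, specificity: float, n_positive: int, n_negative: int
) -> ConfusionCounts:
    """Reconstruct integer counts from printed (rounded) rates and class totals."""
    tp = round(sensitivity * n_positive)
    tn = round(specificity * n_negative)
    return ConfusionCounts(TP=tp, FP=n_negative - tn, FN=n_positive - tp, TN=tn)


def confusion_from_calls(
    calls: Sequence[PairCall], truth: Mapping[tuple[str, str], str]
) -> ConfusionCounts:
    """Confusion table of calls against a pair-label map; pairs absent from
    ``truth`` are ignored."""
    tp = fp = fn = tn = 0
    for c in calls:
        t = truth.get((c.gene_a, c.gene_b))
        if t is None:
            continue
        if t == OPERONIC:
            if c.call == OPERONIC:
                tp += 1
            else:
                fn += 1
        else:
            if c.call == OPERONIC:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


# ---------------------------------------------------------------------------
# Threshold sweeps
# ---------------------------------------------------------------------------

def curves(
    truth: Sequence[int] | Sequence[bool], probabilities: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """ROC and PR curves with trapezoid AUCs.

    Returns ``(roc_points, pr_points, roc_auc, pr_auc)`` where ``roc_points``
    is an (n, 2) array of (FPR, TPR) and ``pr_points`` an (n, 2) array of
    (recall, precision).  Ties in scores are grouped, making the ROC AUC equal
    to the concordance (Mann-Whitney) statistic.
    """
    y = np.asarray(truth, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape or y.ndim != 1:
        raise MetricsError("truth and probabilities must be equal-length vectors")
    P = int(y.sum())
    N = int(len(y) - P)
    if P == 0 or N == 0:
        raise MetricsError("both classes must be present to sweep thresholds")

    order = np.argsort(-p, kind="stable")
    y_sorted = y[order]
    p_sorted = p[order]
    # group ties: keep cumulative counts only at the last element of each group
    distinct = np.r_[np.diff(p_sorted) != 0, True]
    cum_tp = np.cumsum(y_sorted)[distinct]
    cum_fp = np.cumsum(1 - y_sorted)[distinct]

    tpr = np.r_[0.0, cum_tp / P]
    fpr = np.r_[0.0, cum_fp / N]
    roc = np.column_stack([fpr, tpr])
    roc_auc = float(np.trapezoid(tpr, fpr))

    recall = cum_tp / P
    with np.errstate(invalid="ignore"):
        precision = cum_tp / (cum_tp + cum_fp)
    recall = np.r_[0.0, recall]
    precision = np.r_[1.0 if precision.size == 0 else precision[0], precision]
    pr = np.column_stack([recall, precision])
    pr_auc = float(np.trapezoid(precision, recall))
    return roc, pr, roc_auc, pr_auc


def pair_metrics(
    calls: Sequence[PairCall],
    truth: Mapping[tuple[str, str], str],
    with_curves: bool = True,
) -> MetricsReport:
    """Full metrics report for pair calls, with per-genome breakdown."""
    labeled = [c for c in calls if (c.gene_a, c.gene_b) in truth]
    if not labeled:
        raise MetricsError("no calls overlap the truth labels")
    report = compute_metrics(confusion_from_calls(labeled, truth))
    y = [1 if truth[(c.gene_a, c.gene_b)] == OPERONIC else 0 for c in labeled]
    if with_curves and 0 < sum(y) < len(y):
        _, _, roc_auc, pr_auc = curves(y, [c.probability for c in labeled])
        report.roc_auc = roc_auc
        report.pr_auc = pr_auc
    for genome in sorted({c.genome_id for c in labeled}):
        sub = [c for c in labeled if c.genome_id == genome]
        report.per_genome[genome] = compute_metrics(confusion_from_calls(sub, truth))
    return report


# ---------------------------------------------------------------------------
# Full-operon matching
# ---------------------------------------------------------------------------

def exact_operon_matches(
    predicted: Sequence[OperonPrediction],
    truth: Sequence[OperonRecord],
    gene_order: Optional[Mapping[str, int]] = None,
) -> float:
    """Fraction of known multi-gene operons predicted with exact boundaries.

    Both gene lists are oriented in genome coordinate order (via
    ``gene_order`` when given) before comparison, so annotation strand cannot
    affect matching.
    """
    multi = [op for op in truth if op.is_multi_gene]
    if not multi:
        raise MetricsError("truth contains no multi-gene operons")

    def canon(ids: Sequence[str]) -> tuple[str, ...]:
        if gene_order is not None and all(g in gene_order for g in ids):
            return tuple(sorted(ids, key=lambda g: gene_order[g]))
        return tuple(ids)

    predicted_sets = {canon(p.gene_ids) for p in predicted}
    matched = sum(1 for op in multi if canon(op.gene_ids) in predicted_sets)
    return matched / len(multi)
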