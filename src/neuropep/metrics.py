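"""Performance evaluation for binary peptide classifiers.

Threshold-dependent statistics (sensitivity, specificity, accuracy, MCC) are
computed from confusion counts:

    Sen = 100 * TP / (TP + FN)
    Spc = 100 * TN / (TN + FP)
    Acc = 100 * (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

The threshold-independent AUROC is the rank statistic: the probability that
a random positive outscores a random negative, ties counted half — which
equals the trapezoidal area under the TPR-vs-FPR curve.

Five-fold cross-validation trains on four folds and evaluates the held-out
fold; headline numbers are the unweighted mean over the five folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

if TYPE_CHECKING:  # pragma: no cover
    from .classifier import ModelSpec, TrainedModel


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN at one threshold."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_positives(self) -> int:
        return self.tp + self.fn

    @property
    def n_negatives(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class EvalReport:
    """Sen/Spc/Acc (percent), MCC and AUROC at a stated threshold."""

    threshold: float
    counts: ConfusionCounts
    sen: float
    spc: float
    acc: float
    mcc: float
    auroc: Optional[float] = None

    def as_row(self) -> dict:
        # column order follows the field's convention: Sen, Spc, Acc, MCC, AUROC
        return {
            "Threshold": self.threshold,
            "Sen": round(self.sen, 2),
            "Spc": round(self.spc, 2),
            "Acc": round(self.acc, 2),
            "MCC": round(self.mcc, 2),
            "AUROC": None if self.auroc is None else round(self.auroc, 2),
        }


def confusion_at_threshold(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> ConfusionCounts:
    """Count TP/TN/FP/FN with score >= threshold predicted positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def sensitivity(counts: ConfusionCounts) -> float:
    """Percent of positives recovered: 100*TP/(TP+FN)."""
    if counts.n_positives == 0:
        raise ZeroDivisionError("no positives: sensitivity undefined")
    return 100.0 * counts.tp / counts.n_positives


def specificity(counts: ConfusionCounts) -> float:
    """Percent of negatives recovered: 100*TN/(TN+FP)."""
    if counts.n_negatives == 0:
        raise ZeroDivisionError("no negatives: specificity undefined")
    return 100.0 * counts.tn / counts.n_negatives


def accuracy(counts: ConfusionCounts) -> float:
    """Percent correct overall: 100*(TP+TN)/total."""
    total = counts.tp + counts.tn + counts.fp + counts.fn
    if total == 0:
        raise ZeroDivisionError("empty confusion table")
    return 100.0 * (counts.tp + counts.tn) / total


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 if any margin is empty."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUROC as the Mann-Whitney rank statistic, ties counted half.

    Equals the trapezoidal area under the TPR-vs-FPR curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties
    pos_rank_sum = float(np.sum(ranks[labels == 1]))
    u = pos_rank_sum - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


def evaluate_at_threshold(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float,
    with_auroc: bool = True,
) -> EvalReport:
    """Full report (counts + all metrics) at one threshold."""
    counts = confusion_at_threshold(scores, labels, threshold)
    return EvalReport(
        threshold=threshold,
        counts=counts,
        sen=sensitivity(counts),
        spc=specificity(counts),
        acc=accuracy(counts),
        mcc=mcc(counts),
        auroc=auroc(scores, labels) if with_auroc else None,
    )


def threshold_sweep(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[pd.DataFrame, float]:
    """Evaluate every distinct-score threshold; return (table, best threshold).

    The best threshold maximizes accuracy; ties go to the threshold with the
    smallest |Sen - Spc| (the most balanced operating point).
    """
    scores = np.asarray(scores, dtype=float)
    thresholds = np.unique(scores)
    rows = []
    for t in thresholds:
        rep = evaluate_at_threshold(scores, labels, float(t), with_auroc=False)
        rows.append(
            {
                "threshold": float(t),
                "sen": rep.sen,
                "spc": rep.spc,
                "acc": rep.acc,
                "mcc": rep.mcc,
            }
        )
    table = pd.DataFrame(rows)
    best_acc = table["acc"].max()
    candidates = table[table["acc"] == best_acc].copy()
    candidates["balance"] = (candidates["sen"] - candidates["spc"]).abs()
    best = candidates.sort_values(
        ["balance", "threshold"], kind="stable"
    ).iloc[0]
    return table, float(best["threshold"])


def cross_validate(
    matrix: pd.DataFrame,
    labels: Sequence[int],
    folds: Sequence[int],
    spec: "ModelSpec",
    seed: int = 0,
) -> tuple[EvalReport, list[EvalReport], dict]:
    """Five-fold cross-validation of one model specification.

    For each rotation the model is trained on four folds; the classification
    threshold is chosen by :func:`threshold_sweep` on the training folds'
    scores and applied to the held-out fold.  Returns the unweighted mean
    report over folds (the headline numbers), the per-fold reports, and a
    diagnostics dict with pooled held-out scores and their pooled AUROC.
    """
    from .classifier import predict_scores, train  # deferred: avoid cycle

    labels = np.asarray(labels, dtype=int)
    folds = np.asarray(folds, dtype=int)
    if not (len(matrix) == len(labels) == len(folds)):
        raise ValueError("matrix, labels and folds must align")

    per_fold: list[EvalReport] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for f in sorted(np.unique(folds)):
        test_mask = folds == f
        X_tr, y_tr = matrix[~test_mask], labels[~test_mask]
        X_te, y_te = matrix[test_mask], labels[test_mask]
        model = train(X_tr, y_tr, spec, seed=seed)
        _, thr = threshold_sweep(predict_scores(model, X_tr), y_tr)
        te_scores = predict_scores(model, X_te)
        per_fold.append(evaluate_at_threshold(te_scores, y_te, thr))
        pooled_scores.append(np.asarray(te_scores))
        pooled_labels.append(y_te)

    mean = EvalReport(
        threshold=float(np.mean([r.threshold for r in per_fold])),
        counts=ConfusionCounts(
            tp=sum(r.counts.tp for r in per_fold),
            tn=sum(r.counts.tn for r in per_fold),
            fp=sum(r.counts.fp for r in per_fold),
            fn=sum(r.counts.fn for r in per_fold),
        ),
        sen=float(np.mean([r.sen for r in per_fold])),
        spc=float(np.mean([r.spc for r in per_fold])),
        acc=float(np.mean([r.acc for r in per_fold])),
        mcc=float(np.mean([r.mcc for r in per_fold])),
        auroc=float(np.mean([r.auroc for r in per_fold])),
    )
    all_scores = np.concatenate(pooled_scores)
    all_labels = np.concatenate(pooled_labels)
    diagnostics = {
        "pooled_scores": all_scores,
        "pooled_labels": all_labels,
        "pooled_auroc": auroc(all_scores, all_labels),
    }
    return mean, per_fold, diagnostics


def report_table(reports: Sequence[EvalReport], names: Sequence[str]) -> pd.DataFrame:
    """Tabulate reports with the conventional Sen/Spc/Acc/MCC/AUROC columns."""
    return pd.DataFrame([r.as_row() for r in reports], index=list(names))
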