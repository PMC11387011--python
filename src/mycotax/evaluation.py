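"""Classification metrics and model-performance summaries.

Accuracy is the proportion of correct predictions; under heavy class
imbalance it is misleading (an all-majority predictor on a 90/10 binary
problem scores 0.9).  The Matthews correlation coefficient (MCC) corrects
for this: 1 is perfect prediction, 0 no better than random, negative worse
than random.  The multiclass generalization (the R_K statistic) used here
is computed from the confusion matrix as::

    MCC = (c*s - sum_k p_k t_k) /
          sqrt((s^2 - sum_k p_k^2) * (s^2 - sum_k t_k^2))

with ``c`` the trace, ``s`` the total count, ``p_k`` the column (predicted)
sums and ``t_k`` the row (observed) sums; it reduces to the classic binary
TP/TN/FP/FN formula for two classes.  A degenerate denominator (all mass in
one row or column) is scored 0, the standard convention, since single-class
test partitions occur at deep ranks.

Also here: best-epoch selection from training histories (max test MCC,
earliest epoch on ties), k-fold cross-validation orchestration, and the
hierarchical-consistency rate of multi-rank predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import RANKS, TaxonomyTree


@dataclass
class ConfusionMatrix:
    """Counts of observed (rows) versus predicted (columns) labels."""

    labels: list[str]
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def support(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class EvaluationResult:
    """Metrics of one model at one rank, partition and epoch."""

    rank: str
    accuracy: float
    mcc: float
    epoch: int | None = None
    partition: str = "test"
    per_class_precision: dict[str, float] | None = None
    per_class_recall: dict[str, float] | None = None


def confusion(y_true, y_pred, labels=None) -> ConfusionMatrix:
    """Build the confusion matrix ``counts[i, j] = #(true=i, pred=j)``."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if labels is None:
        labels = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    labels = [str(l) for l in labels]
    lut = {l: i for i, l in enumerate(labels)}
    try:
        ti = np.array([lut[str(v)] for v in y_true])
        pi = np.array([lut[str(v)] for v in y_pred])
    except KeyError as err:
        raise ValueError(f"label {err} not in the provided label list") from None
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    np.add.at(counts, (ti, pi), 1)
    return ConfusionMatrix(labels, counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Trace over total: the proportion of correct predictions."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def mcc(cm: ConfusionMatrix) -> float:
    """Multiclass Matthews correlation coefficient (R_K statistic)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(np.float64)
    s = counts.sum()
    c = np.trace(counts)
    p = counts.sum(axis=0)  # predicted (column) sums
    t = counts.sum(axis=1)  # observed (row) sums
    cov = c * s - p @ t
    denom2 = (s * s - p @ p) * (s * s - t @ t)
    if denom2 <= 0:
        return 0.0
    return float(cov / np.sqrt(denom2))


def per_class_metrics(cm: ConfusionMatrix):
    """Precision and recall per class (0 where undefined)."""
    counts = cm.counts.astype(np.float64)
    colsum, rowsum = counts.sum(axis=0), counts.sum(axis=1)
    diag = np.diag(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(colsum > 0, diag / colsum, 0.0)
        rec = np.where(rowsum > 0, diag / rowsum, 0.0)
    return (
        {l: float(p) for l, p in zip(cm.labels, prec)},
        {l: float(r) for l, r in zip(cm.labels, rec)},
    )


# ---------------------------------------------------------------------------
# histories and cross-validation
# ---------------------------------------------------------------------------


def confusion_to_csv(cm: ConfusionMatrix, path) -> None:
    """Write a confusion matrix as CSV (observed rows, predicted columns)."""
    import pandas as pd

    pd.DataFrame(cm.counts, index=cm.labels, columns=cm.labels).to_csv(path)


def confusion_from_csv(path) -> ConfusionMatrix:
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    return ConfusionMatrix([str(l) for l in df.index], df.to_numpy())


def evaluate_history(history: list[dict]) -> dict[str, EvaluationResult]:
    """Best-epoch result per rank: the epoch maximizing test MCC (earliest
    epoch on ties), reporting both metrics at that epoch."""
    if not history:
        raise ValueError("empty training history")
    ranks = list(history[0]["metrics"].keys())
    out = {}
    for r in ranks:
        series = [entry["metrics"][r]["test_mcc"] for entry in history]
        best = int(np.argmax(series))  # argmax returns the first maximum
        m = history[best]["metrics"][r]
        out[r] = EvaluationResult(
            rank=r,
            accuracy=m["test_accuracy"],
            mcc=m["test_mcc"],
            epoch=best,
            partition="test",
        )
    return out


def cross_validate(dataset, folds: np.ndarray, train_fn, k: int | None = None):
    """Full train/evaluate per fold; returns per-fold best-epoch results and
    their mean/SD per rank and metric.

    ``train_fn(fold_dataset) -> history`` must retrain from scratch on the
    fold's train partition (fold-specific oversampling included), so no
    information leaks across folds.  ``folds`` assigns each record its test
    fold.
    """
    folds = np.asarray(folds)
    if k is None:
        k = int(folds.max()) + 1
    per_fold: list[dict[str, EvaluationResult]] = []
    for f in range(k):
        partition = np.where(folds == f, "test", "train")
        history = train_fn(dataset.with_partition(partition))
        per_fold.append(evaluate_history(history))
    ranks = list(per_fold[0].keys())
    summary = {}
    for r in ranks:
        for metric in ("mcc", "accuracy"):
            vals = np.array([getattr(res[r], metric) for res in per_fold])
            summary[(r, metric)] = (float(vals.mean()), float(vals.std(ddof=1)))
    return per_fold, summary


def consistency_rate(predictions: dict[str, np.ndarray], tree: TaxonomyTree) -> float:
    """Fraction of samples whose predicted labels across ranks form a valid
    parent-child path in the (imputation-augmented) taxonomy."""
    ranks = [r for r in RANKS if r in predictions]
    if len(ranks) < 2:
        raise ValueError("need predictions at two or more ranks")
    pos = [RANKS.index(r) for r in ranks]
    if pos != list(range(pos[0], pos[-1] + 1)):
        raise ValueError("predicted ranks must be contiguous in the hierarchy")
    n = len(predictions[ranks[0]])
    for r in ranks:
        for lbl in np.unique(predictions[r]):
            if str(lbl) not in tree.rank_of:
                raise ValueError(f"predicted label {lbl!r} unknown to the taxonomy")
    ok = 0
    for i in range(n):
        path = [str(predictions[r][i]) for r in ranks]
        valid = all(
            tree.parent.get(child) == par for par, child in zip(path, path[1:])
        )
        ok += valid
    return ok / n
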