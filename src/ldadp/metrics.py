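"""Evaluation metrics: permutation-matched sorting accuracy, Davies–Bouldin
index, precision/recall against partially ground-truthed ("marked") spikes,
and template correlation.

Accuracy first matches predicted to true cluster ids one-to-one (optimal
assignment on the contingency table — predicted ids are arbitrary), then
counts the fraction of spikes whose matched label equals the truth.

Precision/recall follow the partial-ground-truth convention used with
paired intracellular/extracellular recordings: one predicted unit is
compared spike-by-spike against the marked set, precision = TP/(TP+FP) and
recall = TP/(TP+FN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .merging import compactness, separation, similarity

__all__ = [
    "EvalReport",
    "sorting_accuracy",
    "dbi",
    "select_best_unit",
    "precision_recall",
    "template_correlation",
]


@dataclass
class EvalReport:
    accuracy: float | None = None
    dbi: float | None = None
    precision: float | None = None
    recall: float | None = None
    counts: dict[str, int] = field(default_factory=dict)
    label_mapping: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "dbi": self.dbi,
            "precision": self.precision,
            "recall": self.recall,
            "counts": self.counts,
            "label_mapping": {str(k): v for k, v in self.label_mapping.items()},
        }


def _contingency(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pu, pi = np.unique(pred, return_inverse=True)
    tu, ti = np.unique(truth, return_inverse=True)
    C = np.zeros((pu.size, tu.size), dtype=int)
    np.add.at(C, (pi, ti), 1)
    return C, pu, tu


def sorting_accuracy(
    pred: np.ndarray, truth: np.ndarray, return_mapping: bool = False
) -> float | tuple[float, dict[int, int]]:
    """Fraction of spikes correctly classified under the best one-to-one
    matching of predicted to true cluster ids.

    Truth ids marked as excluded (e.g. overlap label 0) should be filtered
    out by the caller before scoring.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth lengths differ")
    if pred.size == 0:
        raise ValueError("empty label vectors")
    C, pu, tu = _contingency(pred, truth)
    rows, cols = linear_sum_assignment(-C)
    acc = float(C[rows, cols].sum()) / pred.size
    if return_mapping:
        mapping = {int(pu[r]): int(tu[c]) for r, c in zip(rows, cols)}
        return acc, mapping
    return acc


def dbi(Y: np.ndarray, L: np.ndarray) -> float:
    """Davies–Bouldin index: mean over clusters of the worst-case
    (CP_a+CP_b)/SP_ab, with centroids as cluster centers (standard DBI;
    the merge stage, by contrast, uses density-peaks exemplars).
    Lower means better-separated, tighter clusters.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    L = np.asarray(L, dtype=int)
    labels = np.unique(L)
    K = labels.size
    if K < 2:
        raise ValueError("DBI needs at least 2 clusters")
    Lc = np.searchsorted(labels, L) + 1
    centroids = np.array([Y[Lc == k].mean(axis=0) for k in range(1, K + 1)])
    R = similarity(compactness(Y, Lc, centroids), separation(centroids))
    np.fill_diagonal(R, -np.inf)
    return float(np.mean(R.max(axis=1)))


def select_best_unit(labels: np.ndarray, marked: np.ndarray) -> np.ndarray:
    """Boolean membership of the predicted unit that best matches the marked
    spikes (the cluster with the largest overlap; ties → lower label)."""
    labels = np.asarray(labels)
    marked = np.asarray(marked, dtype=bool)
    if labels.shape != marked.shape:
        raise ValueError("labels and marked lengths differ")
    if not marked.any():
        raise ValueError("no marked spikes")
    best, best_tp = None, -1
    for k in np.unique(labels):
        tp = int(np.sum((labels == k) & marked))
        if tp > best_tp:
            best, best_tp = k, tp
    return labels == best


def precision_recall(
    pred_flags: np.ndarray, marked_flags: np.ndarray
) -> tuple[float, float, dict[str, int]]:
    """Spike-wise precision and recall of a predicted unit against the
    marked set. Returns (precision, recall, counts with TP/FP/TN/FN)."""
    pred = np.asarray(pred_flags, dtype=bool)
    marked = np.asarray(marked_flags, dtype=bool)
    if pred.shape != marked.shape:
        raise ValueError("flag vectors differ in length")
    if not marked.any():
        raise ValueError("no marked spikes")
    tp = int(np.sum(pred & marked))
    fp = int(np.sum(pred & ~marked))
    fn = int(np.sum(~pred & marked))
    tn = int(np.sum(~pred & ~marked))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn)
    return precision, recall, {"TP": tp, "FP": fp, "TN": tn, "FN": fn}


def template_correlation(templates: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of waveform templates (rows)."""
    T = np.atleast_2d(np.asarray(templates, dtype=float))
    if T.shape[0] < 2:
        raise ValueError("need at least 2 templates")
    if np.any(T.std(axis=1) == 0):
        raise ValueError("zero-variance template")
    return np.corrcoef(T)
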