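"""Metrics for coordinate and domain-label predictions."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "EvaluationReport",
    "distance_errors",
    "pairwise_distance_correlation",
    "topk_accuracy_ordinal",
    "topk_accuracy_categorical",
    "write_report",
]


@dataclass
class EvaluationReport:
    task: str
    n_objects: int
    mean_de: float | None = None
    median_de: float | None = None
    pairwise_pearson: float | None = None
    top1: float | None = None
    top2: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _check_coords(pred, truth):
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape or pred.ndim != 2 or pred.shape[1] != 2:
        raise ValueError(
            f"expected matching (n, 2) arrays, got {pred.shape} and {truth.shape}"
        )
    return pred, truth


def distance_errors(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Mean and median Euclidean distance between prediction and truth."""
    pred, truth = _check_coords(pred, truth)
    if pred.shape[0] < 1:
        raise ValueError("need at least one object")
    d = np.linalg.norm(pred - truth, axis=1)
    return float(d.mean()), float(np.median(d))


def pairwise_distance_correlation(pred: np.ndarray, truth: np.ndarray) -> float:
    """Pearson r between predicted and true distances over all object pairs.

    Returns NaN (with a warning) when either distance vector has zero
    variance, where the correlation is undefined.
    """
    pred, truth = _check_coords(pred, truth)
    if pred.shape[0] < 3:
        raise ValueError("need at least 3 objects for pairwise correlation")
    dp = pdist(pred)
    dt = pdist(truth)
    if dp.std() == 0 or dt.std() == 0:
        warnings.warn(
            "pairwise distance correlation undefined (zero variance)",
            stacklevel=2,
        )
        return float("nan")
    return float(np.corrcoef(dp, dt)[0, 1])


def topk_accuracy_ordinal(pred_labels, truth, ordering) -> tuple[float, float]:
    """Exact-match and within-one-rank accuracy for ordered labels.

    ``ordering`` lists the labels from first to last rank; top-2 counts a
    prediction landing on the true label or an adjacent one.
    """
    rank = {label: r for r, label in enumerate(ordering)}
    pred_labels = list(pred_labels)
    truth = list(truth)
    if len(pred_labels) != len(truth):
        raise ValueError("prediction/truth length mismatch")
    unknown = [l for l in set(pred_labels) | set(truth) if l not in rank]
    if unknown:
        raise ValueError(f"labels not in the declared ordering: {unknown}")
    diffs = np.array([abs(rank[p] - rank[t]) for p, t in zip(pred_labels, truth)])
    return float((diffs == 0).mean()), float((diffs <= 1).mean())


def topk_accuracy_categorical(probs: np.ndarray, truth, k: int) -> float:
    """Fraction of objects whose true class is in the top-k by probability."""
    probs = np.asarray(probs, dtype=np.float64)
    truth = np.asarray(truth)
    n, n_classes = probs.shape
    if k > n_classes:
        raise ValueError(f"k={k} exceeds the {n_classes} classes")
    # ties broken by class index: stable sort on (-prob, index)
    order = np.argsort(-probs, axis=1, kind="stable")
    hits = (order[:, :k] == truth[:, None]).any(axis=1)
    return float(hits.mean())


def write_report(report: EvaluationReport, path) -> None:
    """Write metrics as a two-column delimited text file."""
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for key, val in report.as_dict().items():
            fh.write(f"{key}\t{val}\n")
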