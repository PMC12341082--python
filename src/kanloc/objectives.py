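"""Task losses and ordinal label handling.

Three prediction tasks are supported: 2-D coordinate regression (mean
squared error), ordered domain labels (rank-consistent cumulative-logit
loss with optional per-object weights), and unordered domain labels
(weighted softmax cross-entropy).

Each loss has a ``*_grad`` companion returning ``(value, d value / d
inputs)`` for the training loop; the public functions return the value
only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OrdinalEncoding",
    "coral_encode",
    "coral_loss",
    "coral_decode",
    "compute_class_weights",
    "weighted_cross_entropy",
    "mse_loss",
]


@dataclass
class OrdinalEncoding:
    """Binary extension of ordinal labels.

    Entry ``r`` of ``extended_labels[i]`` is 1 iff the true label of
    object ``i`` exceeds rank ``r``, producing rows of the form
    ``(1, ..., 1, 0, ..., 0)``.
    """

    n_classes: int
    extended_labels: np.ndarray  # (n, n_classes - 1), values in {0, 1}

    def __post_init__(self) -> None:
        self.extended_labels = np.asarray(self.extended_labels, dtype=np.float64)
        if self.extended_labels.ndim != 2 or (
            self.extended_labels.shape[1] != self.n_classes - 1
        ):
            raise ValueError(
                f"extended labels must be (n, {self.n_classes - 1}), "
                f"got {self.extended_labels.shape}"
            )


def coral_encode(labels: np.ndarray, n_classes: int) -> OrdinalEncoding:
    """Encode integer labels ``0 .. n_classes-1`` as cumulative binaries."""
    labels = np.asarray(labels)
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        bad = labels[(labels < 0) | (labels >= n_classes)]
        raise ValueError(
            f"labels outside [0, {n_classes - 1}]: {np.unique(bad).tolist()}"
        )
    ranks = np.arange(n_classes - 1)
    ext = (labels[:, None] > ranks[None, :]).astype(np.float64)
    return OrdinalEncoding(n_classes=n_classes, extended_labels=ext)


def _softplus(z: np.ndarray) -> np.ndarray:
    # log(1 + e^z), stable for large |z|
    return np.logaddexp(0.0, z)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def coral_loss_grad(
    cum_logits: np.ndarray,
    enc: OrdinalEncoding,
    spot_weights: np.ndarray | None = None,
):
    """Weighted rank-consistent loss and its gradient w.r.t. the logits.

    The loss is the weighted mean over objects of the summed binary
    logistic losses across the ``n_classes - 1`` cumulative tasks.
    """
    z = np.asarray(cum_logits, dtype=np.float64)
    y = enc.extended_labels
    if z.shape != y.shape:
        raise ValueError(f"logit shape {z.shape} != encoding shape {y.shape}")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite cumulative logits")
    n = z.shape[0]
    if spot_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(spot_weights, dtype=np.float64)
        if w.shape != (n,):
            raise ValueError(f"spot_weights must be ({n},), got {w.shape}")
        if np.any(w < 0):
            raise ValueError("spot_weights must be non-negative")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("spot_weights sum to zero")
    per_obj = np.sum(_softplus(z) - y * z, axis=1)
    loss = float(np.dot(w, per_obj) / wsum)
    grad = (_sigmoid(z) - y) * (w / wsum)[:, None]
    return loss, grad


def coral_loss(
    cum_logits: np.ndarray,
    enc: OrdinalEncoding,
    spot_weights: np.ndarray | None = None,
) -> float:
    return coral_loss_grad(cum_logits, enc, spot_weights)[0]


def coral_decode(cum_logits: np.ndarray) -> np.ndarray:
    """Predicted label = number of cumulative probabilities above 0.5.

    Counting positives always yields a label in ``0 .. n_classes - 1``,
    so decoding is valid for any logit matrix.
    """
    z = np.asarray(cum_logits, dtype=np.float64)
    return (z > 0).sum(axis=1).astype(np.intp)


def compute_class_weights(labels: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    """Inverse-frequency class weights, normalized to mean 1.

    Classes declared but absent from ``labels`` get weight 0 with a
    warning; normalization runs over the observed classes only, so a
    balanced label vector maps to all-ones.
    """
    labels = np.asarray(labels)
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    counts = np.bincount(labels, minlength=n_classes).astype(np.float64)
    weights = np.zeros(n_classes)
    present = counts > 0
    if not present.any():
        raise ValueError("no labels provided")
    if not present.all():
        warnings.warn(
            f"classes with no objects get weight 0: "
            f"{np.flatnonzero(~present).tolist()}",
            stacklevel=2,
        )
    weights[present] = labels.size / counts[present]
    weights[present] /= weights[present].mean()
    return weights


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))


def weighted_cross_entropy_grad(
    logits: np.ndarray,
    labels: np.ndarray,
    class_weights: np.ndarray | None = None,
):
    """Weighted softmax cross-entropy and its gradient w.r.t. the logits."""
    z = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite logits")
    n, K = z.shape
    if labels.shape != (n,):
        raise ValueError(f"labels must be ({n},), got {labels.shape}")
    if class_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(class_weights, dtype=np.float64)[labels]
    wsum = w.sum()
    logp = _log_softmax(z)
    loss = float(-np.dot(w, logp[np.arange(n), labels]) / wsum)
    p = np.exp(logp)
    onehot = np.zeros_like(p)
    onehot[np.arange(n), labels] = 1.0
    grad = (p - onehot) * (w / wsum)[:, None]
    return loss, grad


def weighted_cross_entropy(
    logits: np.ndarray,
    labels: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> float:
    return weighted_cross_entropy_grad(logits, labels, class_weights)[0]


def mse_loss_grad(pred: np.ndarray, truth: np.ndarray):
    """Mean squared error over all objects and coordinates, with gradient."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    diff = pred - truth
    loss = float(np.mean(diff**2))
    grad = 2.0 * diff / diff.size
    return loss, grad


def mse_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    return mse_loss_grad(pred, truth)[0]
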