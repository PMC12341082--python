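"""End-to-end orchestration: preprocess, stage-1 fit + gene selection,
stage-2 refit on the reduced gene set, and query prediction.

Stage 1 trains a model whose first (selector) layer scores every gene;
stage 2 trains a fresh model from scratch on the selected columns only.
A :class:`FitResult` stores everything needed to replay the transform on
a query matrix that merely shares the selected gene names.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import objectives as obj
from .io import Dataset
from .network import (
    DEFAULT_EPSILON,
    DEFAULT_G,
    DEFAULT_KAPPA,
    KANModel,
    TrainConfig,
    init_model,
    train,
)
from .selection import (
    SelectionResult,
    rank_genes_single_node,
    reduce_matrix,
    select_genes_multi_node,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessParams",
    "FitConfig",
    "FitResult",
    "Predictions",
    "preprocess",
    "apply_preprocess",
    "fit_stage1",
    "fit_stage2",
    "two_stage_fit",
    "predict_query",
]

DEFAULT_MITO_PREFIXES = ("MT-", "mt-")


@dataclass
class PreprocessParams:
    """Everything needed to replay the count transform on a query."""

    kept_genes: list
    size_factor_target: float
    mito_prefixes: list = field(default_factory=lambda: list(DEFAULT_MITO_PREFIXES))
    min_cells_per_gene: int = 3
    log_base: str = "natural"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessParams":
        return cls(**d)


def preprocess(
    counts: np.ndarray,
    gene_names: list,
    mito_prefixes=DEFAULT_MITO_PREFIXES,
    min_cells: int = 3,
) -> tuple[np.ndarray, PreprocessParams]:
    """Filter, library-size normalize, and log-transform raw counts.

    Genes detected (count > 0) in fewer than ``min_cells`` objects and
    genes whose name starts with a mitochondrial prefix (matched
    case-insensitively) are dropped; each object's counts over the kept
    genes are scaled to the median total, then ``log(x + 1)`` is applied.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if counts.shape[1] != len(gene_names):
        raise ValueError(
            f"{len(gene_names)} gene names for {counts.shape[1]} columns"
        )
    prefixes = tuple(p.upper() for p in mito_prefixes)
    detected = (counts > 0).sum(axis=0)
    keep = detected >= min_cells
    mito = np.array([str(g).upper().startswith(prefixes) for g in gene_names])
    keep &= ~mito
    if not keep.any():
        raise ValueError("preprocessing removed every gene")
    kept_genes = [g for g, k in zip(gene_names, keep) if k]
    sub = counts[:, keep]
    totals = sub.sum(axis=1)
    target = float(np.median(totals))
    with np.errstate(divide="ignore", invalid="ignore"):
        sf = np.where(totals > 0, target / totals, 0.0)
    X = np.log1p(sub * sf[:, None])
    params = PreprocessParams(
        kept_genes=kept_genes,
        size_factor_target=target,
        mito_prefixes=list(mito_prefixes),
        min_cells_per_gene=min_cells,
    )
    return X, params


def apply_preprocess(
    counts: np.ndarray,
    gene_names: list,
    params: PreprocessParams,
) -> tuple[np.ndarray, list]:
    """Replay a stored transform on a query matrix.

    The query is subset to the kept genes it carries (column order taken
    from the stored parameters); totals are computed over those columns
    and scaled to the stored reference target, so the transform is a
    fixed function of the archive.  Returns the transformed matrix and
    the gene names of its columns.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    name_to_idx = {g: i for i, g in enumerate(gene_names)}
    present = [g for g in params.kept_genes if g in name_to_idx]
    if not present:
        raise ValueError("query shares no genes with the stored model")
    sub = counts[:, [name_to_idx[g] for g in present]]
    totals = sub.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sf = np.where(totals > 0, params.size_factor_target / totals, 0.0)
    return np.log1p(sub * sf[:, None]), present


@dataclass
class FitConfig:
    """Configuration of a two-stage fit.

    ``g`` requests a ranked top-``g`` selection (selector width
    ``p1 = 1``); with ``p1 > 1`` the per-node count ``t`` is used instead
    and the realized union size becomes the effective ``g``.  The master
    ``seed`` derives every stream (both initializations and both batch
    shuffles).

    Stage 1 defaults to a shallow additive model (no hidden layers) with
    strong decay on the edge weights: the selector's ``w_s`` scores are
    then driven by each gene's additive predictive utility rather than by
    what a deep overparameterized fit happens to memorize, which makes
    the ranking far more reliable.  Stage 2 defaults to a deeper,
    undecayed model for predictive power on the reduced gene set.
    """

    task: str = "ordinal"
    p1: int | None = None  # default: one selector node per output (1 for ordinal)
    hidden1: tuple = ()
    hidden2: tuple = (16, 8)
    g: int = 20
    t: int | None = None
    grid: tuple = (DEFAULT_G, DEFAULT_KAPPA, DEFAULT_EPSILON)
    use_relu: bool = True
    epochs1: int = 150
    epochs2: int = 150
    batch_size: int = 128
    learning_rate: float = 1e-2
    grid_update_epochs: tuple = (0, 10, 25, 50)
    weight_decay1: float = 4.0
    weight_decay2: float = 0.0
    weight_classes: bool = True
    keep_genes: tuple = ()
    min_cells: int = 3
    mito_prefixes: tuple = DEFAULT_MITO_PREFIXES
    seed: int = 0


@dataclass
class FitResult:
    """A fitted two-stage pipeline, sufficient to predict on queries."""

    preprocess: PreprocessParams
    stage1_model: KANModel
    selection: SelectionResult
    stage2_model: KANModel
    coord_scaler: tuple | None
    task: str
    label_order: list | None = None

    def __post_init__(self) -> None:
        if self.stage2_model.in_dim != len(self.selection.genes):
            raise ValueError(
                f"stage-2 model input dim {self.stage2_model.in_dim} != "
                f"{len(self.selection.genes)} selected genes"
            )
        if (self.coord_scaler is not None) != (self.task == "coordinates"):
            raise ValueError(
                "coord_scaler must be present exactly for the coordinates task"
            )

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "preprocess": self.preprocess.to_dict(),
            "stage1_model": self.stage1_model.to_dict(),
            "stage2_model": self.stage2_model.to_dict(),
            "selection": {
                "genes": list(self.selection.genes),
                "scores": list(self.selection.scores),
                "mode": self.selection.mode,
                "t_per_node": self.selection.t_per_node,
            },
            "coord_scaler": self.coord_scaler,
            "label_order": self.label_order,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        sel = d["selection"]
        scaler = d["coord_scaler"]
        if scaler is not None:
            scaler = tuple(tuple(ax) for ax in scaler)
        return cls(
            preprocess=PreprocessParams.from_dict(d["preprocess"]),
            stage1_model=KANModel.from_dict(d["stage1_model"]),
            selection=SelectionResult(
                genes=sel["genes"], scores=sel["scores"], mode=sel["mode"],
                t_per_node=sel["t_per_node"],
            ),
            stage2_model=KANModel.from_dict(d["stage2_model"]),
            coord_scaler=scaler,
            task=d["task"],
            label_order=d["label_order"],
        )


@dataclass
class Predictions:
    task: str
    coords: np.ndarray | None = None
    labels: np.ndarray | None = None
    cum_logits: np.ndarray | None = None
    probs: np.ndarray | None = None


def _derived_seeds(master: int, n: int = 4) -> list[int]:
    children = np.random.SeedSequence(master).spawn(n)
    return [int(c.generate_state(1)[0]) for c in children]


def _encode_targets(task: str, data: Dataset, n_classes: int | None):
    if task == "coordinates":
        if data.coords is None:
            raise ValueError("coordinates task requires coordinates")
        return data.coords, None
    if data.labels is None:
        raise ValueError(f"{task} task requires labels")
    order = data.label_order
    if order is None:
        order = sorted(set(data.labels.tolist()))
    rank = {l: r for r, l in enumerate(order)}
    y = np.array([rank[l] for l in data.labels.tolist()], dtype=np.intp)
    return y, list(order)


def _out_dim(task: str, n_classes: int | None) -> int:
    if task == "coordinates":
        return 2
    if task == "ordinal":
        return 1
    return int(n_classes)


def fit_stage1(X, Y, p1, hidden, task, cfg: TrainConfig,
               grid=(DEFAULT_G, DEFAULT_KAPPA, DEFAULT_EPSILON),
               use_relu=True, n_classes=None, init_seed=0):
    """Train the selector-bearing model: dims [m, p1, hidden..., out].

    With no hidden layers and ``p1`` equal to the output width the
    selector layer doubles as the output layer (dims ``[m, p1]``), giving
    a purely additive model whose first-layer weights directly express
    each gene's predictive utility.
    """
    if p1 < 1:
        raise ValueError("selector width p1 must be >= 1")
    out = _out_dim(task, n_classes)
    if not hidden and p1 == out:
        dims = [X.shape[1], p1]
    else:
        dims = [X.shape[1], p1, *hidden, out]
    model = init_model(dims, task, grid=grid, seed=init_seed,
                       use_relu=use_relu, n_classes=n_classes)
    model, history = train(model, X, Y, cfg)
    return model, history


def fit_stage2(X_reduced, Y, hidden, task, cfg: TrainConfig,
               grid=(DEFAULT_G, DEFAULT_KAPPA, DEFAULT_EPSILON),
               use_relu=True, n_classes=None, init_seed=0):
    """Train a fresh model from scratch on the reduced matrix."""
    if X_reduced.shape[1] < 1:
        raise ValueError("stage 2 needs at least one gene")
    dims = [X_reduced.shape[1], *hidden, _out_dim(task, n_classes)]
    model = init_model(dims, task, grid=grid, seed=init_seed,
                       use_relu=use_relu, n_classes=n_classes)
    model, history = train(model, X_reduced, Y, cfg)
    return model, history


def two_stage_fit(data: Dataset, config: FitConfig) -> FitResult:
    """Preprocess, fit stage 1, select genes, refit stage 2."""
    task = config.task
    logger.info("stage boundaries: preprocess | stage1 | select | stage2")
    logger.info("config: %s", config)
    X, pp = preprocess(data.counts, data.gene_names,
                       mito_prefixes=config.mito_prefixes,
                       min_cells=config.min_cells)
    logger.info("preprocess kept %d/%d genes", len(pp.kept_genes), data.n_genes)

    y_raw, label_order = _encode_targets(task, data, None)
    n_classes = len(label_order) if label_order is not None else None

    coord_scaler = None
    class_weights = None
    if task == "coordinates":
        lo = y_raw.min(axis=0)
        hi = y_raw.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        Y = (y_raw - lo) / span
        coord_scaler = ((float(lo[0]), float(hi[0])), (float(lo[1]), float(hi[1])))
    elif task == "ordinal":
        if config.weight_classes:
            class_weights = obj.compute_class_weights(y_raw, n_classes)
        Y = obj.coral_encode(y_raw, n_classes).extended_labels
    else:
        if config.weight_classes:
            class_weights = obj.compute_class_weights(y_raw, n_classes)
        Y = y_raw

    p1 = config.p1 if config.p1 is not None else _out_dim(task, n_classes)
    seeds = _derived_seeds(config.seed)
    cfg1 = TrainConfig(
        epochs=config.epochs1, batch_size=config.batch_size,
        learning_rate=config.learning_rate, seed=seeds[1],
        grid_update_epochs=frozenset(config.grid_update_epochs),
        class_weights=class_weights, weight_decay=config.weight_decay1,
    )
    model1, hist1 = fit_stage1(
        X, Y, p1, config.hidden1, task, cfg1, grid=config.grid,
        use_relu=config.use_relu, n_classes=n_classes, init_seed=seeds[0],
    )
    logger.info("stage1 final loss %.6g", hist1[-1])

    if p1 == 1:
        g = config.g
        if g > len(pp.kept_genes):
            warnings.warn(
                f"requested g={g} exceeds {len(pp.kept_genes)} surviving "
                "genes; clipping", stacklevel=2,
            )
            g = len(pp.kept_genes)
        sel = rank_genes_single_node(model1.layers[0], g, pp.kept_genes,
                                     keep=list(config.keep_genes) or None)
    else:
        # per-node budget: explicit t, else the g budget split across nodes
        t = config.t if config.t is not None else max(1, config.g // p1)
        t = min(t, len(pp.kept_genes))
        sel = select_genes_multi_node(model1.layers[0], t, pp.kept_genes)
    logger.info("selected %d genes (mode %s)", sel.g_total, sel.mode)

    X_red = reduce_matrix(X, sel, pp.kept_genes)
    hidden2 = config.hidden2 if config.hidden2 is not None else config.hidden1
    cfg2 = TrainConfig(
        epochs=config.epochs2, batch_size=config.batch_size,
        learning_rate=config.learning_rate, seed=seeds[3],
        grid_update_epochs=frozenset(config.grid_update_epochs),
        class_weights=class_weights, weight_decay=config.weight_decay2,
    )
    model2, hist2 = fit_stage2(
        X_red, Y, hidden2, task, cfg2, grid=config.grid,
        use_relu=config.use_relu, n_classes=n_classes, init_seed=seeds[2],
    )
    logger.info("stage2 final loss %.6g", hist2[-1])

    return FitResult(
        preprocess=pp, stage1_model=model1, selection=sel,
        stage2_model=model2, coord_scaler=coord_scaler, task=task,
        label_order=label_order,
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def predict_query(fit: FitResult, counts: np.ndarray,
                  gene_names: list) -> Predictions:
    """Predict locations/domains for a query expression matrix.

    The query must contain every selected gene by name (missing genes
    raise an error naming them — the compatibility failure small gene
    sets are meant to avoid); column order is irrelevant.
    """
    available = set(gene_names)
    missing = [g for g in fit.selection.genes if g not in available]
    if missing:
        raise KeyError(
            f"query is missing {len(missing)} selected gene(s): {missing}"
        )
    Xq, present = apply_preprocess(counts, gene_names, fit.preprocess)
    X_red = reduce_matrix(Xq, fit.selection, present)
    out = fit.stage2_model.forward(X_red)
    if fit.task == "coordinates":
        (x_lo, x_hi), (y_lo, y_hi) = fit.coord_scaler
        lo = np.array([x_lo, y_lo])
        hi = np.array([x_hi, y_hi])
        span = np.where(hi > lo, hi - lo, 1.0)
        return Predictions(task="coordinates", coords=out * span + lo)
    if fit.task == "ordinal":
        ranks = obj.coral_decode(out)
        labels = np.array([fit.label_order[r] for r in ranks])
        return Predictions(task="ordinal", labels=labels, cum_logits=out)
    probs = _softmax(out)
    ranks = probs.argmax(axis=1)
    labels = np.array([fit.label_order[r] for r in ranks])
    return Predictions(task="categorical", labels=labels, probs=probs)
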