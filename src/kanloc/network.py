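"""Spline-edge network: layers, forward pass, initialization, training.

Every edge of the network carries a learnable univariate activation

    phi(x) = w_b * silu(x) + w_s * spline(x)

optionally wrapped in a ReLU (the stabilized variant).  A node simply
sums its incoming edge activations — there is no weight matrix.  All
edges feeding out of one input node share that node's knot grid (grid
updates are driven by the node's observed values, which are common to
those edges), while ``w_b``, ``w_s`` and the spline coefficients are
per-edge.

Training is plain minibatch gradient descent with Adam, implemented with
hand-derived gradients in numpy; at configured epochs each layer's grids
are re-estimated from the observed node values and the spline
coefficients are least-squares refitted to preserve the edge functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .splines import (
    DEFAULT_EPSILON,
    DEFAULT_G,
    DEFAULT_KAPPA,
    DegenerateRangeError,
    EdgeActivationParams,
    GridSpec,
    _basis_from_knots,
    update_grid,
)

logger = logging.getLogger(__name__)

__all__ = [
    "KANLayerSpec",
    "KANModel",
    "TrainConfig",
    "silu",
    "edge_activation",
    "layer_forward",
    "kan_forward",
    "init_model",
    "train",
    "TASKS",
]

TASKS = ("coordinates", "ordinal", "categorical")


def silu(x):
    """x * sigmoid(x), computed stably for large |x|."""
    x = np.asarray(x, dtype=np.float64)
    out = np.where(x >= 0, x / (1.0 + np.exp(-np.abs(x))),
                   x * np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    return out


def _silu_grad(x):
    x = np.asarray(x, dtype=np.float64)
    s = 1.0 / (1.0 + np.exp(-np.abs(x)))
    s = np.where(x >= 0, s, 1.0 - s)
    return s * (1.0 + x * (1.0 - s))


class KANLayerSpec:
    """One network layer: a ``(out_dim, in_dim)`` bank of edge activations.

    Parameters are stored as arrays — ``w_b``, ``w_s`` of shape
    ``(out_dim, in_dim)``, ``coeffs`` of shape ``(out_dim, in_dim, K)``
    and per-input-node knot vectors ``knots`` of shape
    ``(in_dim, G + 2*kappa + 1)``.
    """

    def __init__(self, in_dim: int, out_dim: int, *, G: int, kappa: int,
                 epsilon: float, use_relu: bool,
                 w_b: np.ndarray, w_s: np.ndarray, coeffs: np.ndarray,
                 knots: np.ndarray):
        if in_dim < 1 or out_dim < 1:
            raise ValueError("layer dimensions must be positive")
        K = G + kappa
        if w_b.shape != (out_dim, in_dim) or w_s.shape != (out_dim, in_dim):
            raise ValueError("edge weight banks must have shape (out_dim, in_dim)")
        if coeffs.shape != (out_dim, in_dim, K):
            raise ValueError(f"coeffs bank must be (out_dim, in_dim, {K})")
        if knots.shape != (in_dim, G + 2 * kappa + 1):
            raise ValueError("knot bank must be (in_dim, G + 2*kappa + 1)")
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.G = G
        self.kappa = kappa
        self.epsilon = epsilon
        self.use_relu = use_relu
        self.w_b = np.asarray(w_b, dtype=np.float64)
        self.w_s = np.asarray(w_s, dtype=np.float64)
        self.coeffs = np.asarray(coeffs, dtype=np.float64)
        self.knots = np.asarray(knots, dtype=np.float64)

    @property
    def n_bases(self) -> int:
        return self.G + self.kappa

    def grid_for_node(self, j: int) -> GridSpec:
        """GridSpec view of input node ``j``'s knot vector."""
        t = self.knots[j]
        return GridSpec(knots=t.copy(), G=self.G, kappa=self.kappa,
                        epsilon=self.epsilon,
                        domain_lo=float(t[self.kappa]),
                        domain_hi=float(t[self.kappa + self.G]))

    def edge_params(self, out_node: int, in_node: int) -> EdgeActivationParams:
        """Per-edge parameter view (copy) for inspection and selection."""
        return EdgeActivationParams(
            w_b=float(self.w_b[out_node, in_node]),
            w_s=float(self.w_s[out_node, in_node]),
            coeffs=self.coeffs[out_node, in_node].copy(),
            grid=self.grid_for_node(in_node),
        )

    # -- forward / backward -------------------------------------------------

    def forward(self, X: np.ndarray, cache: dict | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.in_dim:
            raise ValueError(
                f"layer expects input of width {self.in_dim}, got shape {X.shape}"
            )
        need_grad = cache is not None
        if need_grad:
            B, dB = _basis_from_knots(X, self.knots, self.kappa, derivative=True)
        else:
            B = _basis_from_knots(X, self.knots, self.kappa)
        sb = silu(X)  # (n, in)
        spl = np.einsum("nik,oik->noi", B, self.coeffs)  # (n, out, in)
        pre = self.w_b[None] * sb[:, None, :] + self.w_s[None] * spl
        act = np.maximum(pre, 0.0) if self.use_relu else pre
        out = act.sum(axis=2)
        if need_grad:
            cache.update(X=X, B=B, dB=dB, sb=sb, spl=spl, pre=pre)
        return out

    def backward(self, g_out: np.ndarray, cache: dict, grads: dict) -> np.ndarray:
        """Accumulate parameter grads; return gradient w.r.t. the input."""
        X, B, dB, sb, spl, pre = (cache[k] for k in ("X", "B", "dB", "sb", "spl", "pre"))
        g_pre = np.repeat(g_out[:, :, None], self.in_dim, axis=2)
        if self.use_relu:
            g_pre = np.where(pre > 0, g_pre, 0.0)
        grads["w_b"] = np.einsum("noi,ni->oi", g_pre, sb)
        grads["w_s"] = np.einsum("noi,noi->oi", g_pre, spl)
        grads["coeffs"] = np.einsum("noi,nik->oik", g_pre * self.w_s[None], B)
        dspl = np.einsum("nik,oik->noi", dB, self.coeffs)
        g_in = (
            np.einsum("noi,oi->ni", g_pre, self.w_b) * _silu_grad(X)
            + np.einsum("noi,noi->ni", g_pre * self.w_s[None], dspl)
        )
        return g_in

    def to_dict(self) -> dict:
        return {
            "in_dim": self.in_dim, "out_dim": self.out_dim,
            "G": self.G, "kappa": self.kappa, "epsilon": self.epsilon,
            "use_relu": self.use_relu,
            "w_b": self.w_b.tolist(), "w_s": self.w_s.tolist(),
            "coeffs": self.coeffs.tolist(), "knots": self.knots.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KANLayerSpec":
        return cls(
            d["in_dim"], d["out_dim"], G=d["G"], kappa=d["kappa"],
            epsilon=d["epsilon"], use_relu=d["use_relu"],
            w_b=np.array(d["w_b"], dtype=np.float64),
            w_s=np.array(d["w_s"], dtype=np.float64),
            coeffs=np.array(d["coeffs"], dtype=np.float64),
            knots=np.array(d["knots"], dtype=np.float64),
        )


class KANModel:
    """A stack of spline-edge layers plus a task-specific output head.

    ``task`` is one of ``coordinates`` (2 outputs), ``categorical``
    (``n_classes`` outputs, softmax at decode time) or ``ordinal`` (one
    shared score plus ``n_classes - 1`` trainable biases producing
    cumulative logits).
    """

    def __init__(self, layers: list[KANLayerSpec], task: str,
                 n_classes: int | None = None,
                 head_biases: np.ndarray | None = None):
        if task not in TASKS:
            raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
        for a, b in zip(layers[:-1], layers[1:]):
            if a.out_dim != b.in_dim:
                raise ValueError(
                    f"layer dims do not chain: {a.out_dim} -> {b.in_dim}"
                )
        out_dim = layers[-1].out_dim
        if task == "coordinates" and out_dim != 2:
            raise ValueError(f"coordinates task needs output dim 2, got {out_dim}")
        if task in ("ordinal", "categorical") and n_classes is None:
            raise ValueError(f"{task} task requires n_classes")
        if task == "ordinal" and out_dim != 1:
            raise ValueError(f"ordinal task needs a single shared score, got {out_dim}")
        if task == "categorical" and out_dim != n_classes:
            raise ValueError(
                f"categorical task needs output dim {n_classes}, got {out_dim}"
            )
        if task == "ordinal":
            if head_biases is None:
                raise ValueError("ordinal task requires head biases")
            head_biases = np.asarray(head_biases, dtype=np.float64)
            if head_biases.shape != (n_classes - 1,):
                raise ValueError(
                    f"head biases must have shape ({n_classes - 1},)"
                )
        self.layers = layers
        self.task = task
        self.n_classes = n_classes
        self.head_biases = head_biases

    @property
    def dims(self) -> list[int]:
        return [self.layers[0].in_dim] + [l.out_dim for l in self.layers]

    @property
    def in_dim(self) -> int:
        return self.layers[0].in_dim

    def forward(self, X: np.ndarray, caches: list | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.in_dim:
            raise ValueError(
                f"model expects {self.in_dim} genes, got input shape {X.shape}"
            )
        h = X
        for layer in self.layers:
            c = {} if caches is not None else None
            h = layer.forward(h, cache=c)
            if caches is not None:
                caches.append(c)
        if self.task == "ordinal":
            h = h + self.head_biases[None, :]
        return h

    def backward(self, g_out: np.ndarray, caches: list) -> dict:
        """Gradients for all parameters given d loss / d outputs."""
        grads: dict = {"layers": [None] * len(self.layers)}
        g = np.asarray(g_out, dtype=np.float64)
        if self.task == "ordinal":
            grads["head_biases"] = g.sum(axis=0)
            g = g.sum(axis=1, keepdims=True)
        for i in range(len(self.layers) - 1, -1, -1):
            layer_grads: dict = {}
            g = self.layers[i].backward(g, caches[i], layer_grads)
            grads["layers"][i] = layer_grads
        return grads

    def parameters(self) -> list[tuple[str, np.ndarray]]:
        params = []
        for i, layer in enumerate(self.layers):
            params.append((f"layers.{i}.w_b", layer.w_b))
            params.append((f"layers.{i}.w_s", layer.w_s))
            params.append((f"layers.{i}.coeffs", layer.coeffs))
        if self.task == "ordinal":
            params.append(("head_biases", self.head_biases))
        return params

    def grad_arrays(self, grads: dict) -> list[np.ndarray]:
        out = []
        for i in range(len(self.layers)):
            lg = grads["layers"][i]
            out.extend([lg["w_b"], lg["w_s"], lg["coeffs"]])
        if self.task == "ordinal":
            out.append(grads["head_biases"])
        return out

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "n_classes": self.n_classes,
            "head_biases": None if self.head_biases is None
            else self.head_biases.tolist(),
            "layers": [l.to_dict() for l in self.layers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KANModel":
        hb = d["head_biases"]
        return cls(
            [KANLayerSpec.from_dict(ld) for ld in d["layers"]],
            task=d["task"], n_classes=d["n_classes"],
            head_biases=None if hb is None else np.array(hb, dtype=np.float64),
        )


@dataclass
class TrainConfig:
    """Hyperparameters of the gradient-descent loop.

    ``grid_update_epochs`` lists the epochs at whose start every layer
    re-estimates its knot grids from the observed node values and
    least-squares refits the spline coefficients.
    """

    epochs: int = 300
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0
    grid_update_epochs: frozenset = frozenset({0, 10, 25, 50})
    class_weights: np.ndarray | None = None
    weight_decay: float = 0.0  # decoupled, on w_b/w_s only

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        self.grid_update_epochs = frozenset(self.grid_update_epochs)


def edge_activation(x: np.ndarray, params: EdgeActivationParams,
                    use_relu: bool) -> np.ndarray:
    """phi(x) = w_b*silu(x) + w_s*spline(x), ReLU-wrapped in the stabilized variant."""
    from .splines import evaluate_spline

    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    out = params.w_b * silu(x) + params.w_s * evaluate_spline(x, params)
    return np.maximum(out, 0.0) if use_relu else out


def layer_forward(x: np.ndarray, layer: KANLayerSpec) -> np.ndarray:
    """Forward one vector (or batch) through a layer."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        return layer.forward(x[None, :])[0]
    return layer.forward(x)


def kan_forward(X: np.ndarray, model: KANModel) -> np.ndarray:
    """Row-wise composition of all layers (plus the ordinal head, if any)."""
    return model.forward(X)


def init_model(dims: list[int], task: str,
               grid: tuple[int, int, float] = (DEFAULT_G, DEFAULT_KAPPA, DEFAULT_EPSILON),
               seed: int = 0, use_relu: bool = True,
               n_classes: int | None = None) -> KANModel:
    """Reproducibly initialize a model; identical seeds give identical models.

    ``w_b`` and ``w_s`` are gaussian with scale ``1/sqrt(in_dim)`` —
    nodes sum ``in_dim`` edge activations, so fan-in scaling keeps the
    forward pass O(1) at any width.  Spline coefficients are small
    gaussian draws and every grid starts uniform over [-1, 1].  The
    final layer never applies ReLU so coordinate outputs and logits can
    be negative.
    """
    if any(d < 1 for d in dims):
        raise ValueError(f"all layer dims must be positive, got {dims}")
    if len(dims) < 2:
        raise ValueError("need at least an input and an output dimension")
    G, kappa, epsilon = grid
    K = G + kappa
    out_dim = dims[-1]
    if task == "coordinates" and out_dim != 2:
        raise ValueError(f"coordinates task needs output dim 2, got {out_dim}")
    if task == "ordinal" and out_dim != 1:
        raise ValueError(f"ordinal task needs output dim 1, got {out_dim}")
    if task == "categorical":
        if n_classes is None:
            n_classes = out_dim
        if out_dim != n_classes:
            raise ValueError(
                f"categorical task needs output dim {n_classes}, got {out_dim}"
            )
    rng = np.random.default_rng(seed)
    h = 2.0 / G
    base_knots = -1.0 + h * np.arange(-kappa, G + kappa + 1, dtype=np.float64)
    layers = []
    n_layers = len(dims) - 1
    for l in range(n_layers):
        p_in, p_out = dims[l], dims[l + 1]
        scale = 1.0 / np.sqrt(p_in)
        layers.append(KANLayerSpec(
            p_in, p_out, G=G, kappa=kappa, epsilon=epsilon,
            use_relu=use_relu and (l < n_layers - 1),
            w_b=scale * rng.standard_normal((p_out, p_in)),
            w_s=scale * rng.standard_normal((p_out, p_in)),
            coeffs=0.1 * rng.standard_normal((p_out, p_in, K)),
            knots=np.tile(base_knots, (p_in, 1)),
        ))
    head = None
    if task == "ordinal":
        # descending biases -> monotone cumulative probabilities at init
        head = np.linspace(1.0, -1.0, n_classes - 1)
    return KANModel(layers, task=task, n_classes=n_classes, head_biases=head)


def _make_loss(model: KANModel, cfg: TrainConfig):
    from . import objectives as obj

    if model.task == "coordinates":
        def loss_fn(out, yb, wb):
            return obj.mse_loss_grad(out, yb)
    elif model.task == "ordinal":
        def loss_fn(out, yb, wb):
            enc = obj.OrdinalEncoding(model.n_classes, yb)
            return obj.coral_loss_grad(out, enc, wb)
    else:
        def loss_fn(out, yb, wb):
            lw = None
            if cfg.class_weights is not None:
                lw = np.asarray(cfg.class_weights, dtype=np.float64)
            return obj.weighted_cross_entropy_grad(out, yb, lw)
    return loss_fn


def _update_all_grids(model: KANModel, X: np.ndarray) -> None:
    """Re-estimate every layer's grids from current node values and refit.

    For each input node the grid update uses the node's observed values
    over the full sample; all edges out of that node then refit their
    coefficients jointly by one least-squares solve against the old
    spline outputs.  Nodes with a degenerate (constant) value range keep
    their previous grid.
    """
    h = X
    for layer in model.layers:
        inputs = h
        for j in range(layer.in_dim):
            col = inputs[:, j]
            try:
                new_grid = update_grid(col, layer.G, layer.kappa, layer.epsilon)
            except DegenerateRangeError:
                logger.warning(
                    "grid update skipped for a node with constant values"
                )
                continue
            B_old = _basis_from_knots(col, layer.knots[j], layer.kappa)
            targets = B_old @ layer.coeffs[:, j, :].T  # (n, out)
            B_new = _basis_from_knots(col, new_grid.knots, layer.kappa)
            sol, _, rank, _ = np.linalg.lstsq(B_new, targets, rcond=None)
            if rank < layer.n_bases:
                logger.warning(
                    "rank-deficient refit on a node (rank %d < %d); "
                    "minimum-norm solution used", rank, layer.n_bases,
                )
            layer.coeffs[:, j, :] = sol.T
            layer.knots[j] = new_grid.knots
        h = layer.forward(inputs)


def train(model: KANModel, X: np.ndarray, Y: np.ndarray,
          cfg: TrainConfig) -> tuple[KANModel, list[float]]:
    """Minibatch Adam on the task loss; returns the model and loss history.

    Targets ``Y``: ``(n, 2)`` coordinates, or ``(n, n_classes-1)`` binary
    cumulative encodings (ordinal), or ``(n,)`` integer labels
    (categorical).  For the ordinal task per-object weights are derived
    from ``cfg.class_weights`` indexed by the implied label.

    Raises
    ------
    RuntimeError
        If the loss becomes non-finite, naming the epoch.
    """
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("training matrix contains non-finite values")
    n = X.shape[0]
    loss_fn = _make_loss(model, cfg)

    spot_weights = None
    if model.task == "ordinal":
        Y = np.asarray(Y, dtype=np.float64)
        if cfg.class_weights is not None:
            labels = Y.sum(axis=1).astype(np.intp)
            spot_weights = np.asarray(cfg.class_weights, dtype=np.float64)[labels]
    elif model.task == "coordinates":
        Y = np.asarray(Y, dtype=np.float64)
    else:
        Y = np.asarray(Y)

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    named_params = model.parameters()
    params = [p for _, p in named_params]
    decayed = [name.endswith((".w_b", ".w_s")) for name, _ in named_params]
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history: list[float] = []

    for epoch in range(cfg.epochs):
        if epoch in cfg.grid_update_epochs:
            _update_all_grids(model, X)
        perm = rng.permutation(n)
        total, total_w = 0.0, 0.0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            xb = X[idx]
            yb = Y[idx]
            wb = spot_weights[idx] if spot_weights is not None else None
            caches: list = []
            out = model.forward(xb, caches=caches)
            loss, g_out = loss_fn(out, yb, wb)
            bw = float(wb.sum()) if wb is not None else float(len(idx))
            total += loss * bw
            total_w += bw
            grads = model.backward(g_out, caches)
            garrs = model.grad_arrays(grads)
            step += 1
            lr_t = cfg.learning_rate * (
                np.sqrt(1.0 - beta2**step) / (1.0 - beta1**step)
            )
            for p, g, m, v, dk in zip(params, garrs, m_state, v_state, decayed):
                m *= beta1
                m += (1.0 - beta1) * g
                v *= beta2
                v += (1.0 - beta2) * g * g
                p -= lr_t * m / (np.sqrt(v) + eps)
                if dk and cfg.weight_decay > 0.0:
                    p -= cfg.learning_rate * cfg.weight_decay * p
        epoch_loss = total / total_w
        if not np.isfinite(epoch_loss):
            raise RuntimeError(
                f"training loss became non-finite at epoch {epoch}"
            )
        history.append(epoch_loss)
    return model, history
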