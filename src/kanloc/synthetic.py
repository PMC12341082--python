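"""Seeded generators of spatial-expression fixtures with planted truth.

Two tissue shapes are produced: ``layered`` (spots on a jittered grid cut
into horizontal bands with ordinal band labels — half of the informative
genes vary monotonically across bands, half peak in one band) and
``gradient`` (uniform 2-D coordinates with informative genes following
smooth spatial log-mean surfaces).  Counts are negative-binomial with a
log-link mean and per-spot library-size factors; ``dispersion = 0``
degenerates to Poisson.  Everything is reproducible from the seed, and
the planted informative set is returned exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Dataset

__all__ = [
    "SimConfig",
    "simulate_layered_tissue",
    "simulate_gradient_tissue",
    "split_query",
]


@dataclass
class SimConfig:
    n_spots: int = 1000
    n_genes: int = 100
    n_informative: int = 10
    task: str = "layered"
    n_layers: int = 5
    effect_size: float = 1.0
    library_size_mean: float = 5000.0
    dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("layered", "gradient"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative cannot exceed n_genes")
        if self.n_spots < 1 or self.n_genes < 1:
            raise ValueError("n_spots and n_genes must be positive")
        if self.task == "layered" and self.n_layers < 2:
            raise ValueError("layered tissue needs at least 2 layers")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def _draw_counts(rng: np.random.Generator, mu: np.ndarray,
                 dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    theta = 1.0 / dispersion
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p)


def _gene_names(m: int) -> list[str]:
    width = max(4, len(str(m)))
    return [f"G{i:0{width}d}" for i in range(m)]


def _base_matrix(cfg: SimConfig, rng: np.random.Generator,
                 offsets: np.ndarray) -> np.ndarray:
    """Counts from per-spot-per-gene log-mean offsets around a common base."""
    mu0 = np.log(cfg.library_size_mean / cfg.n_genes)
    libf = np.exp(rng.normal(0.0, 0.15, size=cfg.n_spots))
    mu = np.exp(mu0 + offsets) * libf[:, None]
    return _draw_counts(rng, mu, cfg.dispersion)


def simulate_layered_tissue(cfg: SimConfig) -> tuple[Dataset, list[str]]:
    """Layered tissue with ordinal band labels.

    Returns the dataset (counts, jittered-grid coordinates, band labels
    with their order) and the planted informative gene names.
    """
    if cfg.task != "layered":
        raise ValueError("config task must be 'layered'")
    rng = np.random.default_rng(cfg.seed)
    n, m, L = cfg.n_spots, cfg.n_genes, cfg.n_layers

    n_side = int(np.ceil(np.sqrt(n)))
    rows, cols = np.divmod(np.arange(n), n_side)
    x = (cols + 0.5 + rng.uniform(-0.3, 0.3, n)) / n_side
    y = (rows + 0.5 + rng.uniform(-0.3, 0.3, n)) / n_side
    y = y * n_side / np.ceil(n / n_side)  # normalize occupied rows to [0, 1]
    coords = np.column_stack([x, y])
    labels = np.minimum((np.clip(y, 0.0, None) * L).astype(np.intp), L - 1)

    info_idx = np.sort(rng.choice(m, size=cfg.n_informative, replace=False))
    profiles = np.zeros((m, L))
    layer_axis = np.arange(L)
    for rank, gi in enumerate(info_idx):
        if rank % 2 == 0:  # monotone across layers
            sign = 1.0 if rng.random() < 0.5 else -1.0
            prof = sign * np.linspace(-0.5, 0.5, L)
        else:  # unimodal: peaks in one layer
            center = rng.integers(0, L)
            prof = np.exp(-0.5 * ((layer_axis - center) / 0.8) ** 2)
            prof = prof - prof.mean()
        profiles[gi] = cfg.effect_size * prof

    offsets = profiles[:, labels].T  # (n, m)
    counts = _base_matrix(cfg, rng, offsets)
    names = _gene_names(m)
    ds = Dataset(
        counts=counts,
        gene_names=names,
        obs_names=[f"spot{i}" for i in range(n)],
        coords=coords,
        labels=labels,
        label_order=list(range(L)),
    )
    return ds, [names[i] for i in info_idx]


def simulate_gradient_tissue(cfg: SimConfig, return_log_means: bool = False):
    """Tissue with continuous coordinates and smooth spatial gene surfaces.

    Returns ``(dataset, informative_names)``; with ``return_log_means``
    also the noiseless per-spot log-mean offset matrix, for oracle checks
    that the planted signal suffices to recover the coordinates.
    """
    if cfg.task != "gradient":
        raise ValueError("config task must be 'gradient'")
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_spots, cfg.n_genes
    coords = rng.uniform(0.0, 1.0, size=(n, 2))
    xc = coords[:, 0] - 0.5
    yc = coords[:, 1] - 0.5

    info_idx = np.sort(rng.choice(m, size=cfg.n_informative, replace=False))
    offsets = np.zeros((n, m))
    for rank, gi in enumerate(info_idx):
        kind = rank % 3
        if kind == 0:  # linear gradient in a random direction
            theta = rng.uniform(0, 2 * np.pi)
            f = np.cos(theta) * xc + np.sin(theta) * yc
        elif kind == 1:  # radial bump
            cx, cy = rng.uniform(0.2, 0.8, size=2)
            s = rng.uniform(0.15, 0.3)
            d2 = (coords[:, 0] - cx) ** 2 + (coords[:, 1] - cy) ** 2
            f = np.exp(-0.5 * d2 / s**2)
        else:  # saddle
            f = 4.0 * xc * yc
        f = f - f.mean()
        scale = np.abs(f).max()
        if scale > 0:
            f = f / scale
        offsets[:, gi] = cfg.effect_size * f

    counts = _base_matrix(cfg, rng, offsets)
    names = _gene_names(m)
    ds = Dataset(
        counts=counts,
        gene_names=names,
        obs_names=[f"cell{i}" for i in range(n)],
        coords=coords,
    )
    informative = [names[i] for i in info_idx]
    if return_log_means:
        return ds, informative, offsets
    return ds, informative


def split_query(ds: Dataset, fraction: float, seed: int) -> tuple[Dataset, Dataset]:
    """Disjoint row split into (reference, query); annotations follow rows.

    ``fraction`` is the share of objects placed in the reference part.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    n = ds.n_obs
    n_ref = int(round(n * fraction))
    if n_ref == 0 or n_ref == n:
        raise ValueError(
            f"fraction {fraction} gives a degenerate split of {n} objects"
        )
    perm = np.random.default_rng(seed).permutation(n)
    parts = []
    for idx in (np.sort(perm[:n_ref]), np.sort(perm[n_ref:])):
        parts.append(Dataset(
            counts=ds.counts[idx],
            gene_names=list(ds.gene_names),
            obs_names=[ds.obs_names[i] for i in idx],
            coords=None if ds.coords is None else ds.coords[idx],
            labels=None if ds.labels is None else ds.labels[idx],
            label_order=None if ds.label_order is None else list(ds.label_order),
        ))
    return parts[0], parts[1]
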