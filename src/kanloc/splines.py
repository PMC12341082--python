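"""B-spline primitives for spline-edge networks.

Every network edge carries a learnable univariate function built from a
B-spline basis over an adaptive knot grid.  This module provides scalar
(reference) and vectorized basis evaluation, spline synthesis, data-driven
grid construction, and least-squares coefficient refitting after a grid
change.

Conventions
-----------
A grid of size ``G`` and order ``kappa`` has ``G + 1`` interior knots
spanning ``[domain_lo, domain_hi]`` plus ``kappa`` uniformly spaced
extension knots on each side, for ``G + 2*kappa + 1`` knots in total.
Knots carry the signed index ``j = -kappa .. G + kappa``; basis ``b``
(``b = 0 .. K-1``, ``K = G + kappa``) starts at knot ``j = b - kappa``.
Partition of unity holds on the full interior span.

Intervals are half-open on the right, so every basis vanishes at and
beyond the last knot; inputs outside the knot range contribute zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "EdgeActivationParams",
    "DegenerateRangeError",
    "bspline_basis0",
    "bspline_basis",
    "basis_matrix",
    "evaluate_spline",
    "update_grid",
    "refit_coefficients",
    "uniform_grid",
    "DEFAULT_G",
    "DEFAULT_KAPPA",
    "DEFAULT_EPSILON",
]

DEFAULT_G = 5
DEFAULT_KAPPA = 3
DEFAULT_EPSILON = 0.02


class DegenerateRangeError(ValueError):
    """Raised when a grid update receives samples with zero range."""


@dataclass
class GridSpec:
    """Knot vector plus the parameters that generated it.

    Parameters
    ----------
    knots : np.ndarray
        Non-decreasing vector of length ``G + 2*kappa + 1``.
    G : int
        Grid size (number of interior intervals).
    kappa : int
        Spline order (polynomial degree of the basis).
    epsilon : float
        Blend weight in [0, 1] between the uniform grid (``epsilon=1``)
        and the pure order-statistic grid (``epsilon=0``).
    domain_lo, domain_hi : float
        Bounds of the interior knot span.
    """

    knots: np.ndarray
    G: int
    kappa: int
    epsilon: float
    domain_lo: float
    domain_hi: float

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=np.float64)
        if self.G < 1:
            raise ValueError(f"grid size G must be positive, got {self.G}")
        if self.kappa < 1:
            raise ValueError(f"spline order kappa must be positive, got {self.kappa}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must lie in [0, 1], got {self.epsilon}")
        expected = self.G + 2 * self.kappa + 1
        if self.knots.shape != (expected,):
            raise ValueError(
                f"knot vector must have length G + 2*kappa + 1 = {expected}, "
                f"got shape {self.knots.shape}"
            )
        if np.any(np.diff(self.knots) < 0):
            raise ValueError("knot vector must be non-decreasing")
        if not np.all(np.isfinite(self.knots)):
            raise ValueError("knot vector must be finite")

    @property
    def n_bases(self) -> int:
        """Number of order-``kappa`` basis functions, ``K = G + kappa``."""
        return self.G + self.kappa

    def knot(self, j: int) -> float:
        """Knot value by signed index ``j`` in ``-kappa .. G + kappa``."""
        a = j + self.kappa
        if a < 0 or a >= self.knots.shape[0]:
            raise IndexError(
                f"knot index {j} outside valid range "
                f"[{-self.kappa}, {self.G + self.kappa}]"
            )
        return float(self.knots[a])


@dataclass
class EdgeActivationParams:
    """Trainable parameters of one edge activation.

    ``w_b`` scales the smooth basis function (SiLU), ``w_s`` scales the
    spline part, and ``coeffs`` are the ``K`` spline coefficients.
    """

    w_b: float
    w_s: float
    coeffs: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64)
        if self.coeffs.shape != (self.grid.n_bases,):
            raise ValueError(
                f"coeffs must have length K = {self.grid.n_bases}, "
                f"got shape {self.coeffs.shape}"
            )
        if not (np.isfinite(self.w_b) and np.isfinite(self.w_s)):
            raise ValueError("edge weights must be finite")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("spline coefficients must be finite")


def bspline_basis0(x: float, grid: GridSpec, j: int) -> float:
    """Order-0 basis: indicator of the half-open interval [t_j, t_{j+1})."""
    lo = grid.knot(j)
    hi = grid.knot(j + 1)
    return 1.0 if lo <= x < hi else 0.0


def bspline_basis(x: float, grid: GridSpec, j: int, k: int) -> float:
    """Order-``k`` basis function B_{j,k}(x) via the Cox-de Boor recursion.

    Terms whose knot span has zero length (repeated knots) are dropped,
    the standard convention that keeps the recursion finite.

    Raises
    ------
    ValueError
        If ``k`` exceeds the grid's spline order.
    IndexError
        If the required knots fall outside the knot vector.
    """
    if k < 0 or k > grid.kappa:
        raise ValueError(f"order k={k} outside [0, kappa={grid.kappa}]")
    if k == 0:
        return bspline_basis0(x, grid, j)
    left = 0.0
    d_left = grid.knot(j + k) - grid.knot(j)
    if d_left > 0.0:
        left = (x - grid.knot(j)) / d_left * bspline_basis(x, grid, j, k - 1)
    right = 0.0
    d_right = grid.knot(j + k + 1) - grid.knot(j + 1)
    if d_right > 0.0:
        right = (grid.knot(j + k + 1) - x) / d_right * bspline_basis(x, grid, j + 1, k - 1)
    return left + right


def _basis_from_knots(
    x: np.ndarray, knots: np.ndarray, kappa: int, derivative: bool = False
):
    """Vectorized basis evaluation for a batch of scalars.

    Parameters
    ----------
    x : (n,) array
    knots : (n_knots,) array  or  (p, n_knots) for per-node knot vectors,
        in which case ``x`` must be (n, p).
    kappa : spline order.
    derivative : if True, also return dB/dx of the order-``kappa`` bases.

    Returns
    -------
    B : (n, K) or (n, p, K) array of basis values (K = n_knots - kappa - 1);
        optionally followed by dB of the same shape.
    """
    x = np.asarray(x, dtype=np.float64)
    knots = np.asarray(knots, dtype=np.float64)
    if knots.ndim == 1:
        if x.ndim != 1:
            raise ValueError("x must be 1-D when a single knot vector is given")
        t = knots[None, :]  # (1, n_knots)
        xv = x[:, None, None]  # (n, 1, 1)
        squeeze = True
    else:
        if x.ndim != 2 or x.shape[1] != knots.shape[0]:
            raise ValueError("x must be (n, p) matching per-node knots (p, n_knots)")
        t = knots  # (p, n_knots)
        xv = x[:, :, None]  # (n, p, 1)
        squeeze = False

    with np.errstate(divide="ignore", invalid="ignore"):
        B = ((xv >= t[None, :, :-1]) & (xv < t[None, :, 1:])).astype(np.float64)
        B_prev = None
        for k in range(1, kappa + 1):
            if derivative and k == kappa:
                B_prev = B
            d0 = t[:, k:-1] - t[:, : -k - 1]
            d1 = t[:, k + 1 :] - t[:, 1:-k]
            w0 = np.where(d0 > 0, (xv - t[None, :, : -k - 1]) / np.where(d0 > 0, d0, 1.0), 0.0)
            w1 = np.where(d1 > 0, (t[None, :, k + 1 :] - xv) / np.where(d1 > 0, d1, 1.0), 0.0)
            B = w0 * B[..., :-1] + w1 * B[..., 1:]

    out = B[:, 0, :] if squeeze else B
    if not derivative:
        return out
    d0 = t[:, kappa:-1] - t[:, : -kappa - 1]
    d1 = t[:, kappa + 1 :] - t[:, 1:-kappa]
    inv0 = np.where(d0 > 0, kappa / np.where(d0 > 0, d0, 1.0), 0.0)
    inv1 = np.where(d1 > 0, kappa / np.where(d1 > 0, d1, 1.0), 0.0)
    dB = inv0 * B_prev[..., :-1] - inv1 * B_prev[..., 1:]
    dout = dB[:, 0, :] if squeeze else dB
    return out, dout


def basis_matrix(x: np.ndarray, grid: GridSpec, derivative: bool = False):
    """Design matrix of all K order-``kappa`` bases at the points ``x``.

    Returns ``(n, K)``; with ``derivative=True`` also the elementwise
    derivative matrix.
    """
    return _basis_from_knots(np.atleast_1d(x), grid.knots, grid.kappa, derivative)


def evaluate_spline(x: np.ndarray, params: EdgeActivationParams) -> np.ndarray:
    """Evaluate sum_k c_k B_k(x) elementwise; zero outside the knot range."""
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    B = basis_matrix(x, params.grid)
    return B @ params.coeffs


def uniform_grid(G: int, kappa: int, lo: float = -1.0, hi: float = 1.0,
                 epsilon: float = DEFAULT_EPSILON) -> GridSpec:
    """Uniform knot grid over ``[lo, hi]`` (initial grid before data updates)."""
    if not hi > lo:
        raise ValueError(f"need hi > lo, got [{lo}, {hi}]")
    h = (hi - lo) / G
    knots = lo + h * np.arange(-kappa, G + kappa + 1, dtype=np.float64)
    return GridSpec(knots=knots, G=G, kappa=kappa, epsilon=epsilon,
                    domain_lo=lo, domain_hi=hi)


def _order_statistic_knots(sorted_samples: np.ndarray, G: int) -> np.ndarray:
    """G+1 evenly spaced order statistics, indices rounded half-up."""
    n = sorted_samples.shape[0]
    idx = np.floor(np.arange(G + 1) * (n - 1) / G + 0.5).astype(np.intp)
    return sorted_samples[idx]


def update_grid(samples: np.ndarray, G: int, kappa: int, epsilon: float) -> GridSpec:
    """Build an adaptive grid from observed edge inputs.

    Interior knots are the convex blend ``epsilon * uniform + (1 - epsilon)
    * quantile`` of a uniform grid over ``[min, max]`` and the grid of
    ``G + 1`` evenly spaced order statistics of the sorted samples; the
    vector is then extended by ``kappa`` uniformly spaced knots per side.

    Raises
    ------
    DegenerateRangeError
        If all samples are identical (a constant input carries no
        information and admits no non-degenerate grid).
    """
    samples = np.asarray(samples, dtype=np.float64).ravel()
    if samples.size == 0:
        raise ValueError("update_grid requires a non-empty sample vector")
    if not np.all(np.isfinite(samples)):
        raise ValueError("update_grid requires finite samples")
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must lie in [0, 1], got {epsilon}")
    lo = float(samples.min())
    hi = float(samples.max())
    if hi == lo:
        raise DegenerateRangeError(
            f"all {samples.size} samples equal {lo!r}: the input range is "
            "degenerate and no spline grid can be constructed"
        )
    srt = np.sort(samples)
    quantile = _order_statistic_knots(srt, G)
    uniform = np.linspace(lo, hi, G + 1)
    interior = epsilon * uniform + (1.0 - epsilon) * quantile
    h = (interior[-1] - interior[0]) / G
    left = interior[0] - h * np.arange(kappa, 0, -1)
    right = interior[-1] + h * np.arange(1, kappa + 1)
    knots = np.concatenate([left, interior, right])
    return GridSpec(knots=knots, G=G, kappa=kappa, epsilon=epsilon,
                    domain_lo=float(interior[0]), domain_hi=float(interior[-1]))


def refit_coefficients(
    old_params: EdgeActivationParams,
    new_grid: GridSpec,
    samples: np.ndarray,
) -> EdgeActivationParams:
    """Least-squares refit of spline coefficients onto a new grid.

    The new coefficients minimize the squared difference between the new
    and old spline outputs over ``samples`` (the batch that produced the
    new grid), so the edge function is preserved as closely as possible.
    Rank-deficient designs fall back to the minimum-norm solution with a
    logged warning.  ``w_b`` and ``w_s`` are carried over unchanged.
    """
    samples = np.asarray(samples, dtype=np.float64).ravel()
    target = evaluate_spline(samples, old_params)
    B = basis_matrix(samples, new_grid)
    coeffs, _, rank, _ = np.linalg.lstsq(B, target, rcond=None)
    if rank < new_grid.n_bases:
        logger.warning(
            "coefficient refit design is rank deficient (rank %d < K=%d); "
            "using the minimum-norm least-squares solution",
            rank, new_grid.n_bases,
        )
    return EdgeActivationParams(
        w_b=old_params.w_b, w_s=old_params.w_s, coeffs=coeffs, grid=new_grid
    )
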