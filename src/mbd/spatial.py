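"""Moran's I spatial autocorrelation over the regional-PD grid.

For tile values x_1..x_N with mean x_bar and a symmetric weight matrix w,

    I = N / (sum_ij w_ij) * sum_ij w_ij (x_i - x_bar)(x_j - x_bar)
                           / sum_i (x_i - x_bar)^2,

sums over ordered pairs i != j.  The default weights are inverse squared
distance, w_ij = 1 / d_ij^2, with d_ij the Euclidean distance between
tile midpoints measured in tile units (orthogonally adjacent midpoints
are at distance 1), filled for every tile pair.  Contiguity-only rook and
queen schemes are also provided because "distance between midpoints of
adjacent sub-regions" can be read either way; every result records the
scheme used.

Sign rule for the pattern label: I > 0 clustered, I = 0 random,
I < 0 scattered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .regional import TileGrid

__all__ = [
    "WeightMatrix",
    "MoranResult",
    "MoranError",
    "weight_matrix",
    "morans_i",
    "classify_pattern",
    "SCHEMES",
]

SCHEMES = ("inverse_distance_squared", "rook", "queen")
PATTERNS = ("clustered", "random", "scattered")


class MoranError(ValueError):
    """Raised for degenerate inputs (constant field, non-finite statistic)."""


@dataclass(frozen=True)
class WeightMatrix:
    """Symmetric nonnegative tile-pair weights with zero diagonal."""

    w: np.ndarray
    scheme: str

    @property
    def n(self) -> int:
        return self.w.shape[0]


def weight_matrix(grid: TileGrid, scheme: str = "inverse_distance_squared") -> WeightMatrix:
    """Build tile-pair weights from grid midpoints (tile units).

    inverse_distance_squared: w_ij = 1/d_ij^2 for all i != j.
    rook:  w = 1 for orthogonal neighbors (d = 1), else 0.
    queen: w = 1/d^2 for orthogonal (1) and diagonal (1/2) neighbors.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if grid.n_tiles < 2:
        raise MoranError("need at least two tiles")
    mid = grid.midpoints()
    diff = mid[:, None, :] - mid[None, :, :]
    d2 = (diff**2).sum(axis=-1)
    if scheme == "inverse_distance_squared":
        with np.errstate(divide="ignore"):
            w = np.where(d2 > 0, 1.0 / np.where(d2 > 0, d2, 1.0), 0.0)
    elif scheme == "rook":
        w = (np.isclose(d2, 1.0)).astype(float)
    else:  # queen
        w = np.where(np.isclose(d2, 1.0), 1.0, np.where(np.isclose(d2, 2.0), 0.5, 0.0))
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(w=w, scheme=scheme)


@dataclass(frozen=True)
class MoranResult:
    I: float
    N: int
    pattern: str
    x_bar: float
    scheme: str


def morans_i(values: np.ndarray, W: WeightMatrix, eps: float = 0.0) -> MoranResult:
    """Global Moran's I of a tile-value field under weight matrix W.

    Raises :class:`MoranError` when the field is constant (the statistic
    is undefined for zero variance).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size != W.n:
        raise MoranError(f"got {x.size} values for a {W.n}-tile weight matrix")
    n = x.size
    dev = x - x.mean()
    ss = float(dev @ dev)
    if ss == 0.0:
        raise MoranError("Moran's I undefined for constant field")
    num = float(dev @ W.w @ dev)
    sw = float(W.w.sum())
    I = n / sw * num / ss
    return MoranResult(
        I=I,
        N=n,
        pattern=classify_pattern(I, eps=eps),
        x_bar=float(x.mean()),
        scheme=W.scheme,
    )


def classify_pattern(I: float, eps: float = 0.0) -> str:
    """Sign-based pattern label: clustered (>eps), random (|I|<=eps), scattered."""
    if not np.isfinite(I):
        raise MoranError("Moran's I is not finite")
    if eps < 0:
        raise ValueError("eps must be nonnegative")
    if I > eps:
        return "clustered"
    if I < -eps:
        return "scattered"
    return "random"
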