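"""Spatial weight matrices: Queen and Rook contiguity, k-nearest neighbors.

Queen adjacency links polygons sharing any boundary point (vertex or
edge); Rook requires a shared segment of positive length, so the Queen
neighbor set always contains the Rook set.  kNN links each region to the
k nearest centroids and is generally asymmetric.  Row standardization
(each nonempty row rescaled to sum 1) is the default for autocorrelation
statistics; raw binary mode is retained for sensitivity checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidArgumentError
from .synth import RegionGeometry

__all__ = [
    "SpatialWeightMatrix",
    "queen_weights",
    "rook_weights",
    "knn_weights",
    "row_standardize",
]


@dataclass(frozen=True)
class SpatialWeightMatrix:
    w: np.ndarray  # n x n, zero diagonal
    method: str  # queen | rook | knn
    ids: tuple[str, ...]
    k: int | None = None
    row_standardized: bool = False

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def s0(self) -> float:
        """Sum of all weights (the S0 of the Moran denominator)."""
        return float(self.w.sum())

    @property
    def isolates(self) -> list[str]:
        empty = ~self.w.any(axis=1)
        return [rid for rid, e in zip(self.ids, empty) if e]

    def to_triplets(self) -> list[tuple[str, str, float]]:
        ii, jj = np.nonzero(self.w)
        return [(self.ids[i], self.ids[j], float(self.w[i, j])) for i, j in zip(ii, jj)]


def _contiguity(
    geometries: list[RegionGeometry], require_edge: bool, tol: float
) -> np.ndarray:
    n = len(geometries)
    if n < 2:
        raise InvalidArgumentError("need at least 2 regions")
    w = np.zeros((n, n))
    polys = [g.polygon for g in geometries]
    for i in range(n):
        for j in range(i + 1, n):
            if polys[i].distance(polys[j]) > tol:
                continue
            if require_edge:
                shared = polys[i].boundary.intersection(polys[j].boundary)
                if shared.length <= tol:
                    continue
            w[i, j] = w[j, i] = 1.0
    if not w.any(axis=1).all():
        warnings.warn("weight matrix contains isolates (regions with no neighbors)")
    return w


def queen_weights(geometries: list[RegionGeometry], tol: float = 1e-9) -> SpatialWeightMatrix:
    """Binary symmetric matrix; 1 iff polygons share any boundary point
    (within snapping tolerance ``tol`` km)."""
    w = _contiguity(geometries, require_edge=False, tol=tol)
    return SpatialWeightMatrix(w=w, method="queen", ids=tuple(g.region_id for g in geometries))


def rook_weights(geometries: list[RegionGeometry], tol: float = 1e-9) -> SpatialWeightMatrix:
    """Binary symmetric matrix; 1 iff polygons share a boundary segment of
    positive length (> ``tol`` km)."""
    w = _contiguity(geometries, require_edge=True, tol=tol)
    return SpatialWeightMatrix(w=w, method="rook", ids=tuple(g.region_id for g in geometries))


def knn_weights(geometries: list[RegionGeometry], k: int) -> SpatialWeightMatrix:
    """Each row links to the k nearest centroids (Euclidean); distance ties
    broken deterministically by lowest region index."""
    n = len(geometries)
    if not 0 < k < n:
        raise InvalidArgumentError(f"k must be in [1, n-1]; got k={k}, n={n}")
    pts = np.array([g.centroid for g in geometries])
    d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
    np.fill_diagonal(d, np.inf)
    w = np.zeros((n, n))
    for i in range(n):
        order = np.lexsort((np.arange(n), d[i]))  # stable tie-break: lowest index
        w[i, order[:k]] = 1.0
    return SpatialWeightMatrix(
        w=w, method="knn", ids=tuple(g.region_id for g in geometries), k=k
    )


def row_standardize(W: SpatialWeightMatrix) -> SpatialWeightMatrix:
    """Divide each nonempty row by its sum; empty rows (isolates) stay zero."""
    sums = W.w.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(sums > 0, W.w / sums, 0.0)
    return replace(W, w=w, row_standardized=True)


def write_gal(W: SpatialWeightMatrix, path) -> None:
    """GAL-style adjacency listing (header count, then id/degree/neighbors)."""
    lines = [str(W.n)]
    for i, rid in enumerate(W.ids):
        nbrs = [W.ids[j] for j in np.nonzero(W.w[i])[0]]
        lines.append(f"{rid} {len(nbrs)}")
        lines.append(" ".join(nbrs))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
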