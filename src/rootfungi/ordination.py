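"""Dissimilarities, principal coordinate analysis and spatial eigenvectors.

Bray–Curtis (count) and Jaccard (presence/absence) dissimilarities feed a
classical-scaling PCoA; Moran-eigenvector-style spatial predictors are the
principal coordinates of the sampling positions' geographic distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .community import CommunityTable, CommunityDataError, SampleMetadata, to_binary

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "SpatialEigenvectors",
    "bray_curtis",
    "jaccard_binary",
    "geographic_distance",
    "pcoa",
    "spatial_eigenvectors",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric dissimilarity matrix with zero diagonal.

    Triangle inequality is not assumed (Bray–Curtis is only semimetric).
    """

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise CommunityDataError("distance matrix shape mismatch")
        if not np.allclose(d, d.T, atol=1e-10):
            raise CommunityDataError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-10):
            raise CommunityDataError("distance matrix diagonal not zero")
        object.__setattr__(self, "d", d)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass(frozen=True)
class OrdinationResult:
    """Classical-scaling embedding retained to a cumulative-contribution cut.

    ``coordinates`` holds samples x k axes; ``cumulative_contribution`` is the
    running eigenvalue share among positive eigenvalues.
    """

    ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    cumulative_contribution: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def as_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.n_axes)]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


@dataclass(frozen=True)
class SpatialEigenvectors:
    """Spatial eigenvector columns for the sampling positions (zero-mean,
    mutually orthogonal, positive Moran-type eigenvalues in descending order)."""

    position_ids: list[str]
    vectors: np.ndarray
    moran_eigenvalues: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        cols = [f"SEV{i + 1}" for i in range(self.vectors.shape[1])]
        return pd.DataFrame(self.vectors, index=self.position_ids, columns=cols)


def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity: 1 - 2 sum(min) / (sum u + sum v)."""
    d = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, np.nan_to_num(d))


def jaccard_binary(table: CommunityTable) -> DistanceMatrix:
    """Jaccard dissimilarity on presence/absence: 1 - |intersection| / |union|."""
    b = to_binary(table).counts.astype(bool)
    d = squareform(pdist(b, metric="jaccard"))
    return DistanceMatrix(table.sample_ids, np.nan_to_num(d))


def geographic_distance(meta: SampleMetadata) -> DistanceMatrix:
    """Euclidean distances (m) between unique sampling positions."""
    pos = meta.positions()
    d = squareform(pdist(pos[["x", "y"]].to_numpy(dtype=float)))
    return DistanceMatrix(list(pos["position_id"]), d)


def _double_centre(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dist: DistanceMatrix, cum_threshold: float = 0.90) -> OrdinationResult:
    """Principal coordinate analysis (classical scaling).

    Eigen-decomposes the double-centred matrix of -1/2 d^2; axes are retained
    until the cumulative eigenvalue share among *positive* eigenvalues reaches
    ``cum_threshold``.  Negative eigenvalues are dropped from both the
    numerator and the denominator of the contribution; no Cailliez/Lingoes
    correction is applied.
    """
    if not 0.0 < cum_threshold <= 1.0:
        raise ValueError("cum_threshold must be in (0, 1]")
    g = _double_centre(dist.d)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-10, 1e-12 * abs(evals[0]) if evals.size else 0)
    if not pos.any():
        raise CommunityDataError("PCoA degenerate: no positive eigenvalues")
    lam = evals[pos]
    vec = evecs[:, pos]
    contrib = np.cumsum(lam) / lam.sum()
    k = int(np.searchsorted(contrib, cum_threshold - 1e-12) + 1)
    k = min(k, lam.size)
    coords = vec[:, :k] * np.sqrt(lam[:k])
    return OrdinationResult(dist.ids, coords, lam[:k], contrib[:k])


def spatial_eigenvectors(meta: SampleMetadata) -> SpatialEigenvectors:
    """Moran-eigenvector-map construction from the sampling positions.

    Eigen-decomposition of the double-centred matrix of -1/2 (Euclidean
    distance)^2 over positions; eigenvectors with positive eigenvalues are
    returned in descending eigenvalue order.
    """
    gd = geographic_distance(meta)
    if gd.n < 3:
        raise CommunityDataError("need at least 3 distinct positions")
    if np.allclose(gd.d, 0.0):
        raise CommunityDataError("all positions coincide; spatial eigenvectors undefined")
    g = _double_centre(gd.d)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-8 * abs(evals[0])
    return SpatialEigenvectors(gd.ids, evecs[:, pos], evals[pos])
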