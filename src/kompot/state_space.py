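"""Cell-state space construction: kNN graphs and diffusion maps.

The diffusion map follows the standard adaptive-bandwidth recipe: a Gaussian
kernel with per-cell bandwidth set to the distance to the k-th nearest
neighbor, anisotropic density normalization (exponent ``alpha``), and
eigendecomposition of the resulting Markov transition operator. The trivial
unit eigenpair is dropped; each retained eigenvector's sign is fixed so that
its largest-magnitude entry is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "LatentEmbedding",
    "DiffusionMap",
    "KNNGraph",
    "DuplicatePointsError",
    "DisconnectedGraphError",
    "build_knn_graph",
    "compute_diffusion_map",
]


class DuplicatePointsError(ValueError):
    """Raised when distinct cells share identical latent coordinates."""

    def __init__(self, cell_ids: Sequence[str]):
        self.cell_ids = list(cell_ids)
        super().__init__(
            f"{len(self.cell_ids)} cell(s) have zero distance to their nearest "
            f"neighbor (duplicate coordinates): {self.cell_ids[:10]}"
        )


class DisconnectedGraphError(ValueError):
    """Raised when the kNN graph splits into multiple connected components."""

    def __init__(self, n_components: int):
        self.n_components = n_components
        super().__init__(
            f"kNN graph has {n_components} connected components; a single "
            "connected manifold is assumed (increase n_neighbors)"
        )


@dataclass
class LatentEmbedding:
    """Co-embedded, batch-corrected latent representation of cells.

    ``coords`` rows align 1:1 with ``cell_ids``; ``condition`` holds one
    categorical label per cell.
    """

    coords: np.ndarray
    cell_ids: np.ndarray
    condition: np.ndarray
    cell_annotations: pd.DataFrame | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.condition = np.asarray(self.condition, dtype=object)
        if self.coords.ndim != 2:
            raise ValueError("coords must be a 2-D matrix (cells x latent dims)")
        n = self.coords.shape[0]
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if len(self.cell_ids) != n or len(self.condition) != n:
            raise ValueError(
                f"cell_ids ({len(self.cell_ids)}) and condition "
                f"({len(self.condition)}) must align with coords rows ({n})"
            )
        if len(set(self.cell_ids)) != n:
            dupes = pd.Series(self.cell_ids).value_counts()
            dupes = list(dupes[dupes > 1].index[:5])
            raise ValueError(f"cell_ids are not unique, e.g. {dupes}")
        if self.cell_annotations is not None and len(self.cell_annotations) != n:
            raise ValueError("cell_annotations must have one row per cell")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def conditions(self) -> list:
        return sorted(set(self.condition))

    def subset(self, mask: np.ndarray) -> "LatentEmbedding":
        ann = None
        if self.cell_annotations is not None:
            ann = self.cell_annotations.iloc[mask].reset_index(drop=True)
        return LatentEmbedding(
            coords=self.coords[mask],
            cell_ids=self.cell_ids[mask],
            condition=self.condition[mask],
            cell_annotations=ann,
        )


@dataclass
class KNNGraph:
    """k-nearest-neighbor structure with a symmetrized affinity matrix."""

    distances: np.ndarray  # (n, k) sorted ascending, self excluded
    indices: np.ndarray  # (n, k)
    affinity: sp.csr_matrix  # symmetric adaptive-Gaussian kernel
    n_neighbors: int


@dataclass
class DiffusionMap:
    """Diffusion-map cell states: top non-trivial Markov eigenvectors."""

    coords: np.ndarray  # (n, n_components)
    eigenvalues: np.ndarray  # non-increasing, all <= 1
    n_neighbors: int
    kernel_params: dict = field(default_factory=dict)

    def __post_init__(self):
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(ev) > 1e-12):
            raise ValueError("eigenvalues must be non-increasing")
        if np.any(ev > 1.0 + 1e-9):
            raise ValueError("Markov eigenvalues must be <= 1")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("diffusion coords contain non-finite values")
        if self.coords.shape[1] < 2:
            raise ValueError("at least 2 diffusion components are required")


def _coords_of(embedding) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(embedding, LatentEmbedding):
        return embedding.coords, embedding.cell_ids
    X = np.asarray(embedding, dtype=float)
    return X, np.asarray([str(i) for i in range(X.shape[0])], dtype=object)


def build_knn_graph(embedding, n_neighbors: int) -> KNNGraph:
    """Exact Euclidean kNN with self-exclusion and adaptive-kernel affinity.

    The affinity uses a per-cell bandwidth equal to the distance to the
    n_neighbors-th neighbor: ``K_ij = exp(-d_ij^2 / (s_i * s_j))``,
    symmetrized by the arithmetic mean of the directed kernels.
    """
    X, cell_ids = _coords_of(embedding)
    n = X.shape[0]
    if n_neighbors < 1 or n_neighbors >= n:
        raise ValueError(
            f"n_neighbors must be in [1, n_cells); got {n_neighbors} for {n} cells"
        )

    nn = NearestNeighbors(n_neighbors=n_neighbors + 1, algorithm="auto").fit(X)
    dist, idx = nn.kneighbors(X)

    # strip the self-match; under exact ties it may not sit in column 0
    rows = np.arange(n)
    self_col = np.argmax(idx == rows[:, None], axis=1)
    keep = np.ones_like(idx, dtype=bool)
    keep[rows, self_col] = False
    # rows whose self-match was not returned at all (duplicate saturation)
    missing = ~(idx == rows[:, None]).any(axis=1)
    if missing.any():
        for r in np.where(missing)[0]:
            keep[r, -1] = False
    dist = dist[keep].reshape(n, n_neighbors)
    idx = idx[keep].reshape(n, n_neighbors)

    zero_nn = dist[:, 0] <= 0.0
    if zero_nn.any():
        raise DuplicatePointsError(cell_ids[zero_nn])

    sigma = dist[:, -1]  # adaptive bandwidth: distance to k-th neighbor
    denom = sigma[rows[:, None]] * sigma[idx]
    kvals = np.exp(-(dist**2) / denom)
    K = sp.csr_matrix(
        (kvals.ravel(), (np.repeat(rows, n_neighbors), idx.ravel())), shape=(n, n)
    )
    affinity = (K + K.T) * 0.5

    return KNNGraph(
        distances=dist, indices=idx, affinity=affinity, n_neighbors=n_neighbors
    )


def compute_diffusion_map(
    embedding,
    n_components: int = 10,
    n_neighbors: int = 30,
    alpha: float = 1.0,
    scale_by_eigenvalues: bool = False,
) -> DiffusionMap:
    """Diffusion map of the latent embedding.

    Parameters
    ----------
    alpha
        Anisotropic normalization exponent; 1.0 recovers the
        Laplace-Beltrami limit, decoupling geometry from sampling density.
    scale_by_eigenvalues
        Multiply each component by its eigenvalue (off by default; downstream
        GP kernels carry learnable length-scales, so scaling is cosmetic).
    """
    X, _ = _coords_of(embedding)
    n = X.shape[0]
    if n_components < 2:
        raise ValueError("n_components must be >= 2")
    graph = build_knn_graph(embedding, n_neighbors)
    W = graph.affinity

    n_cc, _ = connected_components(W, directed=False)
    if n_cc > 1:
        raise DisconnectedGraphError(n_cc)

    # anisotropic normalization: W~ = D^-a W D^-a
    q = np.asarray(W.sum(axis=1)).ravel()
    inv_qa = sp.diags(q ** (-alpha))
    Wt = inv_qa @ W @ inv_qa

    # symmetric conjugate of the Markov operator P = D~^-1 W~
    d = np.asarray(Wt.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(d)
    S = sp.diags(d_inv_sqrt) @ Wt @ sp.diags(d_inv_sqrt)
    S = (S + S.T) * 0.5  # exact symmetry for eigsh

    k = n_components + 1  # keep the trivial pair to drop it explicitly
    if k >= n - 1:
        raise ValueError(f"n_components={n_components} too large for {n} cells")
    v0 = np.full(n, 1.0 / np.sqrt(n))  # deterministic Lanczos start
    evals, evecs = eigsh(S, k=k, which="LA", v0=v0)

    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]

    # back-transform to eigenvectors of P, drop the trivial unit pair
    phi = evecs * d_inv_sqrt[:, None]
    evals = np.clip(evals[1:], None, 1.0)
    phi = phi[:, 1:]
    phi /= np.linalg.norm(phi, axis=0, keepdims=True)

    # sign convention: largest-magnitude entry positive
    amax = np.argmax(np.abs(phi), axis=0)
    signs = np.sign(phi[amax, np.arange(phi.shape[1])])
    signs[signs == 0] = 1.0
    phi = phi * signs

    coords = phi * evals if scale_by_eigenvalues else phi

    return DiffusionMap(
        coords=coords,
        eigenvalues=evals,
        n_neighbors=n_neighbors,
        kernel_params={
            "bandwidth_rule": "knn_distance",
            "alpha": alpha,
            "scale_by_eigenvalues": scale_by_eigenvalues,
        },
    )
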