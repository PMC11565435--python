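"""k-nearest-neighbor affinity graph and Laplacian for label propagation.

The graph is built once per fit on the input features and held fixed across
iterations; ``tr(Y^T L Y)`` then penalizes label disagreement between
neighboring samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "AffinityGraph",
    "knn_affinity",
    "laplacian",
    "median_sigma",
    "export_edges",
]


@dataclass
class AffinityGraph:
    """Symmetric kNN affinity ``M``, degrees ``D`` and Laplacian ``L = D - M``."""

    M: np.ndarray
    D: np.ndarray
    L: np.ndarray | None
    k: int
    sigma_graph: float


def median_sigma(Z: np.ndarray) -> float:
    """Median pairwise distance, the standard graph-bandwidth heuristic."""
    Z = np.asarray(Z, dtype=float)
    dist = pdist(Z.T)
    med = float(np.median(dist)) if dist.size else 1.0
    return med if med > 0 else 1.0


def knn_affinity(Z: np.ndarray, k: int, sigma_graph: float) -> AffinityGraph:
    """Gaussian-weighted kNN graph with OR-symmetrization.

    ``M_ij = exp(-||z_i - z_j||^2 / (2 sigma^2))`` whenever i is among j's k
    nearest neighbors *or* j among i's (so M is symmetric by construction);
    the diagonal is zero.  Duplicate points get weight 1.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    N = Z.shape[1]
    if not 1 <= k < N:
        raise ValueError(f"k must satisfy 1 <= k < N, got k={k}, N={N}")
    if sigma_graph <= 0:
        raise ValueError(f"sigma_graph must be positive, got {sigma_graph}")
    sq = squareform(pdist(Z.T, metric="sqeuclidean"))
    # k nearest neighbors of each point, self excluded
    order = np.argsort(sq, axis=1, kind="stable")
    neighbor = np.zeros((N, N), dtype=bool)
    for i in range(N):
        picked = [j for j in order[i] if j != i][:k]
        neighbor[i, picked] = True
    keep = neighbor | neighbor.T
    M = np.where(keep, np.exp(-sq / (2.0 * sigma_graph**2)), 0.0)
    np.fill_diagonal(M, 0.0)
    D = np.diag(M.sum(axis=1))
    return AffinityGraph(M=M, D=D, L=None, k=k, sigma_graph=sigma_graph)


def export_edges(graph: AffinityGraph, path) -> None:
    """Write the upper-triangular edges as TSV rows ``i  j  weight``."""
    ii, jj = np.nonzero(np.triu(graph.M, k=1))
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for i, j in zip(ii, jj):
            fh.write(f"{i}\t{j}\t{graph.M[i, j]:.17g}\n")


def laplacian(M: np.ndarray) -> np.ndarray:
    """Combinatorial graph Laplacian ``L = D - M`` (positive semidefinite).

    For any label matrix Y, ``tr(Y^T L Y) = 1/2 sum_ij M_ij ||y_i - y_j||^2``.
    """
    M = np.asarray(M, dtype=float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-12):
        raise ValueError("affinity matrix must be square and symmetric")
    return np.diag(M.sum(axis=1)) - M
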