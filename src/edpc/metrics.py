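"""Distribution-distance family used by the EDPC model.

The maximum mean discrepancy (MMD) between a source and a target sample is
the squared distance between their empirical means.  It can be rewritten as a
single-centroid ("one-center") clustering objective with fixed per-domain
sample weights, and further relaxed into a *possibilistic* clustering
distance in which every sample carries its own typicality weight
``lambda_k in [0, 1]``.  Samples far from the blended domain center receive
small weights, which is what makes the relaxed distance robust to outliers.

This module provides those three distances, the blended per-class centers
used for class-conditional alignment, and the inter-class repulsion matrices
whose quadratic form measures squared gaps between projected class means.

All feature matrices are oriented features-by-samples (``d x n``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DomainPair",
    "ClassCenters",
    "RepulsionMatrix",
    "empirical_kernel_map",
    "kernel_sigma_heuristic",
    "mmd_sq",
    "one_center_bound",
    "pc_distance",
    "class_centers",
    "repulsion_matrix",
]


@dataclass
class DomainPair:
    """A labeled source domain and an unlabeled target domain.

    Parameters
    ----------
    Xs : ndarray of shape (d, n)
        Source features, one sample per column.
    Ys : ndarray of shape (n, C)
        One-hot source labels; row ``i`` marks the class of sample ``i``.
    Xt : ndarray of shape (d, m)
        Target features, sharing the feature space of ``Xs``.
    """

    Xs: np.ndarray
    Ys: np.ndarray
    Xt: np.ndarray

    def __post_init__(self) -> None:
        self.Xs = np.asarray(self.Xs, dtype=float)
        self.Xt = np.asarray(self.Xt, dtype=float)
        self.Ys = np.asarray(self.Ys)
        if self.Xs.ndim != 2 or self.Xt.ndim != 2:
            raise ValueError("Xs and Xt must be 2-D (features x samples)")
        if self.Xs.shape[0] != self.Xt.shape[0]:
            raise ValueError(
                f"source and target must share a feature space: "
                f"d_s={self.Xs.shape[0]} != d_t={self.Xt.shape[0]}"
            )
        if self.Ys.ndim != 2 or self.Ys.shape[0] != self.Xs.shape[1]:
            raise ValueError("Ys must have one row per source sample")
        vals = np.unique(self.Ys)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("Ys entries must be 0/1")
        if not np.all(self.Ys.sum(axis=1) == 1):
            raise ValueError("every row of Ys must be one-hot")
        counts = self.Ys.sum(axis=0)
        if np.any(counts == 0):
            raise ValueError("every class needs at least one source sample")
        self.Ys = self.Ys.astype(float)

    @property
    def d(self) -> int:
        return self.Xs.shape[0]

    @property
    def n(self) -> int:
        return self.Xs.shape[1]

    @property
    def m(self) -> int:
        return self.Xt.shape[1]

    @property
    def N(self) -> int:
        return self.n + self.m

    @property
    def C(self) -> int:
        return self.Ys.shape[1]

    @property
    def X(self) -> np.ndarray:
        """Pooled features ``[Xs | Xt]`` of shape (d, N)."""
        return np.hstack([self.Xs, self.Xt])

    @property
    def source_labels(self) -> np.ndarray:
        """1-based source class ids, length n."""
        return np.argmax(self.Ys, axis=1) + 1


@dataclass
class ClassCenters:
    """Blended global and per-class means.

    ``mu`` has shape (d, C+1): column 0 is the whole-domain blended mean,
    column c (1-based) the blended mean of class c.  Each blended column is
    ``delta * source_mean + (1 - delta) * target_mean``; if a class is empty
    on one side the center falls back to the non-empty side.
    """

    mu: np.ndarray
    delta: float


@dataclass
class RepulsionMatrix:
    """Sum of per-class mean-gap rank-one matrices.

    ``Mrep = sum_c u_c u_c^T`` where ``u_c`` has ``+1/n_c`` on class-c
    samples and ``-1/(N - n_c)`` on the pooled complement, so that
    ``tr(P^T X Mrep X^T P)`` is the total squared gap between each projected
    class mean and the projected mean of all other samples.
    """

    Mrep: np.ndarray
    class_sizes: np.ndarray
    per_class: list = field(default_factory=list, repr=False)


def kernel_sigma_heuristic(X: np.ndarray, n_classes: int = 2) -> float:
    """Gaussian kernel bandwidth: sqrt of the average sample norm.

    For more than two classes the bandwidth is scaled by the class count.
    """
    X = np.asarray(X, dtype=float)
    sigma = float(np.sqrt(np.mean(np.linalg.norm(X, axis=0))))
    if n_classes > 2:
        sigma *= n_classes
    return sigma


def empirical_kernel_map(
    X_ref: np.ndarray, X: np.ndarray, sigma_k: float
) -> np.ndarray:
    """Gaussian empirical kernel map of ``X`` against reference points.

    Entry (i, j) is ``exp(-||x_ref_i - x_j||^2 / (2 sigma_k^2))``, turning a
    d-dimensional sample into an N-dimensional similarity profile over the N
    reference points.  The identity (linear) mapping is the default
    elsewhere; this map is opt-in.
    """
    if sigma_k <= 0:
        raise ValueError(f"sigma_k must be positive, got {sigma_k}")
    X_ref = np.atleast_2d(np.asarray(X_ref, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X_ref.size == 0:
        raise ValueError("X_ref must be non-empty")
    if X_ref.shape[0] != X.shape[0]:
        raise ValueError(
            f"feature dimension mismatch: {X_ref.shape[0]} vs {X.shape[0]}"
        )
    # ||a - b||^2 = ||a||^2 + ||b||^2 - 2 a.b, clipped for round-off
    sq = (
        np.sum(X_ref**2, axis=0)[:, None]
        + np.sum(X**2, axis=0)[None, :]
        - 2.0 * X_ref.T @ X
    )
    np.clip(sq, 0.0, None, out=sq)
    return np.exp(-sq / (2.0 * sigma_k**2))


def mmd_sq(Zs: np.ndarray, Zt: np.ndarray) -> float:
    """Squared empirical maximum mean discrepancy between two sample sets."""
    Zs = np.atleast_2d(np.asarray(Zs, dtype=float))
    Zt = np.atleast_2d(np.asarray(Zt, dtype=float))
    if Zs.shape[1] == 0 or Zt.shape[1] == 0:
        raise ValueError("both sample sets must be non-empty")
    if Zs.shape[0] != Zt.shape[0]:
        raise ValueError("sample sets must share a feature dimension")
    diff = Zs.mean(axis=1) - Zt.mean(axis=1)
    return float(diff @ diff)


def one_center_bound(Zs: np.ndarray, Zt: np.ndarray, delta: float = 0.5) -> float:
    """One-center relaxation of the squared MMD.

    Returns ``sum_k sigma_k ||z_k - mu||^2`` with blended center
    ``mu = delta * mean(Zs) + (1 - delta) * mean(Zt)`` and fixed weights
    ``sigma_k = 1/n^2`` for source samples and ``1/m^2`` for target samples.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"delta must be in [0, 1], got {delta}")
    Zs = np.atleast_2d(np.asarray(Zs, dtype=float))
    Zt = np.atleast_2d(np.asarray(Zt, dtype=float))
    if Zs.shape[1] == 0 or Zt.shape[1] == 0:
        raise ValueError("both sample sets must be non-empty")
    if Zs.shape[0] != Zt.shape[0]:
        raise ValueError("sample sets must share a feature dimension")
    n, m = Zs.shape[1], Zt.shape[1]
    mu = delta * Zs.mean(axis=1) + (1.0 - delta) * Zt.mean(axis=1)
    ds = np.sum((Zs - mu[:, None]) ** 2, axis=0)
    dt = np.sum((Zt - mu[:, None]) ** 2, axis=0)
    return float(ds.sum() / n**2 + dt.sum() / m**2)


def pc_distance(Z: np.ndarray, weights: np.ndarray, center: np.ndarray) -> float:
    """Possibilistic clustering distance ``sum_k lambda_k^2 ||z_k - c||^2``.

    ``weights`` are the raw memberships ``lambda_k in [0, 1]``; the
    membership exponent is fixed at 2, so the weights are squared here.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or np.any(weights > 1):
        raise ValueError("membership weights must lie in [0, 1]")
    center = np.asarray(center, dtype=float)
    sq = np.sum((Z - center[:, None]) ** 2, axis=0)
    return float(np.sum(weights**2 * sq))


def _blended(mu_s: np.ndarray | None, mu_t: np.ndarray | None, delta: float) -> np.ndarray:
    # empty-side fallback: pseudo-labels can transiently empty a target class
    if mu_s is None and mu_t is None:
        raise ValueError("class empty on both sides")
    if mu_s is None:
        return mu_t
    if mu_t is None:
        return mu_s
    return delta * mu_s + (1.0 - delta) * mu_t


def _wmean(Z: np.ndarray, mask: np.ndarray, w: np.ndarray | None) -> np.ndarray | None:
    if not mask.any():
        return None
    if w is None:
        return Z[:, mask].mean(axis=1)
    wm = w[mask]
    tot = wm.sum()
    if tot <= 1e-12:  # all members fully down-weighted: fall back to plain
        return Z[:, mask].mean(axis=1)
    return (Z[:, mask] * wm) @ np.ones(int(mask.sum())) / tot


def class_centers(
    pair: DomainPair,
    target_labels: np.ndarray,
    Z: np.ndarray | None = None,
    delta: float = 0.6,
    sample_weights: tuple[np.ndarray, np.ndarray] | None = None,
) -> ClassCenters:
    """Blended global and per-class means (column 0 = whole domain).

    Source class membership comes from the true labels; target membership
    from the current pseudo-labels (1-based).  ``Z`` defaults to the pooled
    raw features; pass projected features to get centers in the subspace.

    By default each side's mean is the plain sample mean.  During a fit the
    optimizer passes ``sample_weights=(w_global, w_class)`` (the effective
    membership weights for the whole-domain column and for each sample's own
    class column) and the means become membership-weighted — the stationary
    centers of the possibilistic objective — so down-weighted noisy samples
    barely shift them.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"delta must be in [0, 1], got {delta}")
    target_labels = np.asarray(target_labels, dtype=int)
    C = pair.C
    if target_labels.shape != (pair.m,):
        raise ValueError("target_labels must have one entry per target sample")
    if np.any(target_labels < 1) or np.any(target_labels > C):
        raise ValueError(f"target labels must be in 1..{C}")
    if Z is None:
        Z = pair.X
    Z = np.asarray(Z, dtype=float)
    Zs, Zt = Z[:, : pair.n], Z[:, pair.n :]
    src_labels = pair.source_labels
    if sample_weights is None:
        w0s = w0t = wcs = wct = None
    else:
        w0, wc = sample_weights
        w0s, w0t = np.asarray(w0)[: pair.n], np.asarray(w0)[pair.n :]
        wcs, wct = np.asarray(wc)[: pair.n], np.asarray(wc)[pair.n :]
    all_s = np.ones(pair.n, dtype=bool)
    all_t = np.ones(pair.m, dtype=bool)
    mu = np.empty((Z.shape[0], C + 1))
    mu[:, 0] = _blended(_wmean(Zs, all_s, w0s), _wmean(Zt, all_t, w0t), delta)
    for c in range(1, C + 1):
        mu_s = _wmean(Zs, src_labels == c, wcs)
        mu_t = _wmean(Zt, target_labels == c, wct)
        mu[:, c] = _blended(mu_s, mu_t, delta)
    return ClassCenters(mu=mu, delta=delta)


def repulsion_matrix(labels_all: np.ndarray) -> RepulsionMatrix:
    """Inter-class repulsion matrices over pooled source + target labels.

    For each class c the rank-one matrix ``M_c = u_c u_c^T`` (with
    ``u_c = 1_c / n_c - 1_comp / (N - n_c)``) satisfies
    ``tr(P^T X M_c X^T P) = ||projected class-c mean - projected complement
    mean||^2``; ``Mrep`` is their sum.  Every row of each ``M_c`` sums to 0.
    """
    labels_all = np.asarray(labels_all, dtype=int)
    N = labels_all.size
    classes = np.unique(labels_all)
    C = int(classes.max())
    if np.any(labels_all < 1):
        raise ValueError("labels must be 1-based")
    sizes = np.array([(labels_all == c).sum() for c in range(1, C + 1)])
    if np.any(sizes == 0):
        empty = [c + 1 for c in range(C) if sizes[c] == 0]
        raise ValueError(f"classes {empty} have no members; repair labels first")
    Mrep = np.zeros((N, N))
    per_class = []
    for c in range(1, C + 1):
        mask = labels_all == c
        nc = int(mask.sum())
        u = np.where(mask, 1.0 / nc, -1.0 / (N - nc))
        Mc = np.outer(u, u)
        per_class.append(Mc)
        Mrep += Mc
    return RepulsionMatrix(Mrep=Mrep, class_sizes=sizes, per_class=per_class)
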