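"""The EDPC estimator.

EDPC (Emotion-recognition Domain adaptation with Discriminative
Possibilistic Clustering) couples four ingredients in one objective:

* a possibilistic-clustering relaxation of MMD that pulls every sample,
  weighted by its typicality, toward blended global and class centers in a
  shared subspace ``P`` ("sames attract"),
* an inter-class repulsion term that pushes projected class means apart
  ("opposites repel"),
* graph-Laplacian label propagation ``alpha * tr(Y^T L Y)`` that spreads
  source labels to target samples along the kNN graph, and
* an l2,1-regularized least-squares classifier ``W`` on the projected
  features, whose row sparsity performs feature selection.

A fuzzy-entropy term ``theta * sum(w ln w - w)`` on the effective membership
weights ``w = lambda^2`` yields the closed-form weight
``w = exp(-J / theta)``, where ``J`` is the sample's fit-plus-distance cost;
noisy samples (large ``J``) are thereby down-weighted automatically.

Optimization is block-coordinate descent with closed-form updates for the
memberships, the classifier (iteratively reweighted least squares), the
label matrix (eigenvectors of a graph-plus-residual matrix) and the
projection (a small Sylvester-type solve followed by polar projection onto
the orthonormal manifold).  The label and projection steps solve relaxed
subproblems, so each is accepted only if it does not increase the joint
objective; the objective trace is therefore non-increasing by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import linalg
from .graph import knn_affinity, laplacian, median_sigma
from .metrics import (
    ClassCenters,
    DomainPair,
    RepulsionMatrix,
    class_centers,
    empirical_kernel_map,
    kernel_sigma_heuristic,
    repulsion_matrix,
)

__all__ = [
    "Hyperparams",
    "EDPCState",
    "update_membership",
    "update_decision",
    "update_labels",
    "update_projection",
    "objective",
    "fit",
    "predict",
]

logger = logging.getLogger(__name__)

_W_FLOOR = 1e-12  # lower clip for membership weights
_U_EPS = 1e-8  # safeguard for zero rows in the l2,1 reweighting


@dataclass
class Hyperparams:
    """All scalar knobs of the EDPC objective and its optimizer.

    Defaults follow the published operating ranges: temperature
    ``theta = 400``, propagation weight ``alpha = 150`` (mid of [100, 225]),
    source-mean weight ``delta = 0.6`` (high-performance band [0.5, 0.85]),
    fusion weight ``upsilon = 0.9``; repulsion ``beta`` and sparsity ``rho``
    default to 1 with a grid over {1e-6 .. 1e6} exposed via the CLI.
    """

    alpha: float = 150.0
    beta: float = 1.0
    theta: float = 400.0
    rho: float = 1.0
    varpi: float | None = None  # None -> 1e-3 * tr(S_dist) / d each iteration
    delta: float = 0.6
    upsilon: float = 0.9
    b: int = 2
    r: int | None = None  # None -> C + 1 (spans the global + class centers)
    k: int = 5
    sigma_graph: float | None = None  # None -> median pairwise distance
    eps_stop: float = 1e-5  # relative to 1 + |objective at start|
    max_iter: int = 100
    inner_iters: int = 5  # l2,1 reweighting passes
    kernel: str = "linear"
    sigma_k: float | None = None  # None -> sqrt-average-norm heuristic
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.rho < 0:
            raise ValueError("alpha, beta and rho must be nonnegative")
        if self.theta <= 0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        if self.varpi is not None and self.varpi < 0:
            raise ValueError("varpi must be nonnegative")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must be in [0, 1], got {self.delta}")
        if not 0.0 <= self.upsilon <= 1.0:
            raise ValueError(f"upsilon must be in [0, 1], got {self.upsilon}")
        if self.b != 2:
            raise ValueError("the membership exponent b is fixed at 2")
        if self.r is not None and self.r < 1:
            raise ValueError("subspace dimension r must be positive")
        if self.k < 1:
            raise ValueError("k must be a positive neighbor count")
        if self.sigma_graph is not None and self.sigma_graph <= 0:
            raise ValueError("sigma_graph must be positive")
        if self.eps_stop <= 0:
            raise ValueError("eps_stop must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.kernel not in ("linear", "gaussian"):
            raise ValueError("kernel must be 'linear' or 'gaussian'")
        if self.sigma_k is not None and self.sigma_k <= 0:
            raise ValueError("sigma_k must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EDPCState:
    """All optimized blocks of a (partially) fitted EDPC model."""

    P: np.ndarray  # d x r orthonormal projection
    W: np.ndarray  # r x C shared decision head
    Ws: np.ndarray  # r x C source-only decision head
    Lam: np.ndarray  # N x (C+1) effective membership weights w = lambda^2
    Y: np.ndarray  # N x C label matrix; source block fixed to Ys
    pseudo_labels: np.ndarray  # m-vector of 1-based target pseudo-labels
    centers: ClassCenters
    Mrep: RepulsionMatrix
    L: np.ndarray  # graph Laplacian, fixed across iterations
    X: np.ndarray  # centered (and possibly kernel-mapped) pooled features
    center_vec: np.ndarray  # subtracted feature mean, applied at predict
    hp: Hyperparams
    n: int
    m: int
    C: int
    objective_trace: list = field(default_factory=list)
    converged: bool = False
    relaxed_value: float = np.nan  # optimum of the relaxed label subproblem
    kernel_ref: np.ndarray | None = None  # reference points for kernel mode
    fixed_membership: bool = False

    @property
    def labels_all(self) -> np.ndarray:
        """Pooled 1-based labels: source truth then target pseudo-labels."""
        src = np.argmax(self.Y[: self.n], axis=1) + 1
        return np.concatenate([src, self.pseudo_labels])


def _entropy(w: np.ndarray) -> np.ndarray:
    w = np.clip(w, _W_FLOOR, None)
    return w * np.log(w) - w


def _fit_residuals(state: EDPCState) -> np.ndarray:
    """Per-sample squared classifier residuals ||W^T P^T x_k - y_k||^2."""
    Z = state.P.T @ state.X
    R = Z.T @ state.W - state.Y
    return np.sum(R**2, axis=1)


def _center_dists(state: EDPCState) -> np.ndarray:
    """N x (C+1) squared distances ||P^T x_k - P^T mu_c||^2."""
    Z = state.P.T @ state.X
    Mu = state.P.T @ state.centers.mu
    sq = (
        np.sum(Z**2, axis=0)[:, None]
        + np.sum(Mu**2, axis=0)[None, :]
        - 2.0 * Z.T @ Mu
    )
    return np.clip(sq, 0.0, None)


def update_membership(state: EDPCState, pair: DomainPair, hp: Hyperparams) -> np.ndarray:
    """Closed-form effective membership weights ``w_{k,c} = exp(-J_{k,c}/theta)``.

    ``J`` combines the classifier residual and the distance to the projected
    class center: for a class column ``c >= 1`` it is
    ``||W^T P^T x_k - y_k||^2 + ||P^T x_k - P^T mu_c||^2``; for the global
    column 0 it is the distance to the blended domain mean alone, so that
    each active element's update is the exact minimizer of its scalar
    subproblem ``w J + theta (w ln w - w)``.  Weights are clipped to
    ``[1e-12, 1]``.  Only column 0 and the sample's own class column enter
    the objective; the other columns are stored for diagnostics.
    """
    if hp.theta <= 0:
        raise ValueError("theta must be positive")
    fit_res = _fit_residuals(state)
    dists = _center_dists(state)
    J = dists.copy()
    J[:, 1:] += fit_res[:, None]
    w = np.exp(-J / hp.theta)
    return np.clip(w, _W_FLOOR, 1.0)


def _active_weights(state: EDPCState) -> tuple[np.ndarray, np.ndarray]:
    """(w0, w_class): global-column weights and own-class-column weights."""
    idx = state.labels_all
    w0 = state.Lam[:, 0]
    wc = state.Lam[np.arange(state.n + state.m), idx]
    return w0, wc


def _l21(W: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(W, axis=1)))


def _irls_solve(
    Z: np.ndarray, Y: np.ndarray, w: np.ndarray, rho: float, inner_iters: int
) -> np.ndarray:
    """min_W sum_k w_k ||W^T z_k - y_k||^2 + rho ||W||_{2,1} by IRLS.

    Each pass solves ``(Z diag(w) Z^T + rho U) W = Z diag(w) Y`` with
    ``U_ii = 1 / max(2 ||row i of W||, eps)``; the half-weight reweighting is
    the standard majorizer of the l2,1 norm, so passes are non-increasing in
    the regularized objective.
    """
    r = Z.shape[0]
    G = (Z * w) @ Z.T
    RHS = (Z * w) @ Y
    if rho == 0.0:
        try:
            return linalg.solve(G, RHS, assume_a="sym")
        except linalg.LinAlgError:
            warnings.warn("singular normal equations with rho=0; using pseudo-inverse")
            return np.linalg.pinv(G) @ RHS
    W = linalg.solve(G + rho * np.eye(r), RHS, assume_a="sym")
    for _ in range(inner_iters):
        u = 1.0 / np.maximum(2.0 * np.linalg.norm(W, axis=1), _U_EPS)
        W = linalg.solve(G + rho * np.diag(u), RHS, assume_a="sym")
    return W


def update_decision(
    state: EDPCState,
    pair: DomainPair,
    hp: Hyperparams,
    inner_iters: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Update the shared head ``W`` and the source-only head ``Ws``.

    Both solve a membership-weighted least-squares problem with l2,1 row
    regularization; ``Ws`` restricts the rows to the source domain and
    regresses on the true source labels only.
    """
    if inner_iters is None:
        inner_iters = hp.inner_iters
    Z = state.P.T @ state.X
    _, wc = _active_weights(state)
    W = _irls_solve(Z, state.Y, wc, hp.rho, inner_iters)
    Ws = _irls_solve(Z[:, : state.n], pair.Ys, wc[: state.n], hp.rho, inner_iters)
    return W, Ws


def decision_objective(
    Z: np.ndarray, Y: np.ndarray, w: np.ndarray, rho: float, W: np.ndarray
) -> float:
    """Value of the classifier subproblem; used for oracle cross-checks."""
    R = Z.T @ W - Y
    return float(np.sum(w * np.sum(R**2, axis=1)) + rho * _l21(W))


def _label_operator(state: EDPCState, hp: Hyperparams) -> np.ndarray:
    """H = alpha L + B^T diag(w) B with B = Z^T A - I (symmetrized)."""
    Z = state.P.T @ state.X
    _, wc = _active_weights(state)
    G = (Z * wc) @ Z.T
    u = 1.0 / np.maximum(2.0 * np.linalg.norm(state.W, axis=1), _U_EPS)
    try:
        A = linalg.solve(G + hp.rho * np.diag(u), Z * wc, assume_a="sym")
    except linalg.LinAlgError:
        A = np.linalg.pinv(G + hp.rho * np.diag(u)) @ (Z * wc)
    B = Z.T @ A - np.eye(Z.shape[1])
    H = hp.alpha * state.L + B.T @ (wc[:, None] * B)
    return 0.5 * (H + H.T)


def _icm_refine(
    state: EDPCState, hp: Hyperparams, pseudo: np.ndarray, max_passes: int = 5
) -> np.ndarray:
    """Exact per-row coordinate descent on the target labels.

    With memberships, W, P and the class centers held fixed, the objective
    restricted to one one-hot target row is a sum of C evaluable costs
    (classifier residual, membership-weighted center distance plus its
    entropy term, and the graph coupling to the other rows), so sweeping
    rows and assigning each to its argmin class is monotone descent.  Sweeps
    stop when a pass changes nothing.
    """
    n, m, C = state.n, state.m, state.C
    N = n + m
    Z = state.P.T @ state.X
    F = Z.T @ state.W  # N x C classifier scores
    dists = _center_dists(state)
    w = state.Lam
    eye = np.eye(C)
    pseudo = pseudo.copy()
    Y = np.zeros((N, C))
    Y[:n] = state.Y[:n]
    Y[np.arange(n, N), pseudo - 1] = 1.0
    # per-class per-row costs that do not depend on the other rows:
    # w_{k,c} (||f_k - e_c||^2 + dist_{k,c}) + theta * ent(w_{k,c})
    fit_all = (
        np.sum(F[n:] ** 2, axis=1)[:, None] - 2.0 * F[n:] + 1.0
    )  # m x C: ||f_k - e_c||^2
    wt = w[n:, 1:]
    local = wt * (fit_all + dists[n:, 1:]) + hp.theta * _entropy(wt)
    for _ in range(max_passes):
        changed = 0
        LY = state.L @ Y  # refreshed once per pass; rows patched on the fly
        for i in range(m):
            row = n + i
            # graph coupling: alpha * (2 e_c . (L Y)_row - 2 L_rr y_old_c + L_rr)
            # constant-in-c parts dropped; L_rr term is constant across c too
            coup = 2.0 * hp.alpha * (LY[row] - state.L[row, row] * Y[row])
            cost = local[i] + coup
            c_new = int(np.argmin(cost)) + 1
            if c_new != pseudo[i]:
                old_vec = Y[row].copy()
                Y[row] = eye[c_new - 1]
                LY += np.outer(state.L[:, row], Y[row] - old_vec)
                pseudo[i] = c_new
                changed += 1
        if changed == 0:
            break
    return pseudo


def update_labels(
    state: EDPCState, pair: DomainPair, hp: Hyperparams
) -> tuple[np.ndarray, np.ndarray, float]:
    """Label-matrix update via the spectral relaxation of the Y subproblem.

    The relaxed solution (under ``Y^T Y = I``) is the C eigenvectors of
    ``H = alpha L + B^T diag(w) B`` with smallest eigenvalues.  Eigenvector
    columns carry no class identity, so they are matched to classes by their
    mean profile over the true-labeled source rows (sign included, via
    linear assignment); target pseudo-labels are the row argmax of the
    aligned target block, and empty classes are repaired by reassigning the
    highest-scoring samples.  Because clamping the source block and
    discretizing breaks the relaxation's optimality, the discrete labels are
    then refined by exact per-row coordinate descent (:func:`_icm_refine`),
    and the returned Y holds the true one-hot source block plus the one-hot
    refined target block.

    Returns ``(Y_new, pseudo_labels, relaxed_value)`` where the relaxed
    value is the sum of the C smallest eigenvalues of H.
    """
    N, C = state.n + state.m, state.C
    H = _label_operator(state, hp)
    try:
        eigvals, eigvecs = linalg.eigh(H, subset_by_index=(0, C - 1))
    except linalg.LinAlgError as exc:  # pragma: no cover - diagnostics path
        raise linalg.LinAlgError(
            f"eigen-solver failed on H (shape {H.shape}, "
            f"|H|_max={np.abs(H).max():.3e}, trace={np.trace(H):.3e})"
        ) from exc
    relaxed_value = float(eigvals.sum())
    Yrel = eigvecs  # N x C

    # align eigenvector columns to classes through the true-labeled source
    # rows: each class's mean eigenvector profile, centered over classes so
    # that zero-contrast directions (e.g. a constant eigenvector) carry no
    # vote, scores every target row by correlation with each class profile
    src_labels = pair.source_labels
    S = np.zeros((C, C))
    for c in range(C):
        S[c] = Yrel[: state.n][src_labels == c + 1].mean(axis=0)
    S_contrast = S - S.mean(axis=0, keepdims=True)
    T = Yrel[state.n :] @ S_contrast.T  # m x C aligned class scores
    pseudo = np.argmax(T, axis=1) + 1  # ties -> smallest class id

    # repair transiently empty pseudo-classes with the top-scoring samples
    for c in range(1, C + 1):
        if np.any(pseudo == c):
            continue
        counts = np.bincount(pseudo, minlength=C + 1)
        movable = counts[pseudo] > 1
        order = np.argsort(-T[:, c - 1], kind="stable")
        for i in order:
            if movable[i]:
                pseudo[i] = c
                break

    pseudo = _icm_refine(state, hp, pseudo)
    Y_new = np.zeros((N, C))
    Y_new[: state.n] = pair.Ys
    Y_new[np.arange(state.n, N), pseudo - 1] = 1.0
    return Y_new, pseudo, relaxed_value


def _dist_scatter(state: EDPCState) -> np.ndarray:
    """S_dist = sum over active (k, c) of w_{k,c} (x_k - mu_c)(x_k - mu_c)^T."""
    X, mu = state.X, state.centers.mu
    w0, wc = _active_weights(state)
    idx = state.labels_all
    D0 = X - mu[:, [0]]
    Dc = X - mu[:, idx]
    return (D0 * w0) @ D0.T + (Dc * wc) @ Dc.T


def update_projection(
    state: EDPCState, pair: DomainPair, hp: Hyperparams
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form projection update followed by polar re-orthonormalization.

    The ridge-penalized surrogate (orthogonality replaced by the penalty
    ``varpi ||P||_F^2``) has stationarity condition

        (S_dist - beta X Mrep X^T + varpi I) P + S_fit P (W W^T) = C_xy

    a Sylvester-type equation solved exactly by diagonalizing the small
    ``W W^T`` factor.  The result is then projected to the nearest
    orthonormal matrix (polar factor via thin SVD).

    Returns ``(P_orthonormal, P_tilde)`` with ``P_tilde`` the raw
    stationary point, kept for stationarity diagnostics.
    """
    X = state.X
    d = X.shape[0]
    _, wc = _active_weights(state)
    S_dist = _dist_scatter(state)
    varpi = hp.varpi if hp.varpi is not None else 1e-3 * np.trace(S_dist) / d
    M1 = S_dist - hp.beta * (X @ state.Mrep.Mrep @ X.T) + varpi * np.eye(d)
    S_fit = (X * wc) @ X.T
    G = state.W @ state.W.T  # r x r
    C_xy = X @ (wc[:, None] * state.Y) @ state.W.T  # d x r

    g, V = linalg.eigh(G)
    Crot = C_xy @ V
    P_rot = np.empty_like(Crot)
    for j in range(g.size):
        Aj = M1 + g[j] * S_fit
        try:
            P_rot[:, j] = linalg.solve(Aj, Crot[:, j], assume_a="sym")
        except linalg.LinAlgError:
            jitter = 1e-8 * np.trace(M1 + S_fit) / d
            try:
                P_rot[:, j] = linalg.solve(
                    Aj + jitter * np.eye(d), Crot[:, j], assume_a="sym"
                )
            except linalg.LinAlgError as exc:
                raise linalg.LinAlgError(
                    "projection system singular even after jitter"
                ) from exc
    P_tilde = P_rot @ V.T
    U_, _, Vt_ = linalg.svd(P_tilde, full_matrices=False)
    return U_ @ Vt_, P_tilde


def projection_gradient(
    state: EDPCState, hp: Hyperparams, P: np.ndarray
) -> np.ndarray:
    """Gradient of the ridge-penalized projection surrogate at ``P``."""
    X = state.X
    _, wc = _active_weights(state)
    S_dist = _dist_scatter(state)
    d = X.shape[0]
    varpi = hp.varpi if hp.varpi is not None else 1e-3 * np.trace(S_dist) / d
    M1 = S_dist - hp.beta * (X @ state.Mrep.Mrep @ X.T) + varpi * np.eye(d)
    S_fit = (X * wc) @ X.T
    C_xy = X @ (wc[:, None] * state.Y) @ state.W.T
    return 2.0 * (M1 @ P + S_fit @ P @ (state.W @ state.W.T) - C_xy)


def objective(state: EDPCState, pair: DomainPair, hp: Hyperparams) -> float:
    """Joint EDPC objective: weighted fit + propagation + l2,1 + weighted
    clustering distance + fuzzy entropy - repulsion."""
    w0, wc = _active_weights(state)
    fit_res = _fit_residuals(state)
    dists = _center_dists(state)
    idx = state.labels_all
    N = state.n + state.m
    dist_own = dists[np.arange(N), idx]
    theta_term = hp.theta * float(np.sum(_entropy(wc) + _entropy(w0)))
    prop = hp.alpha * float(np.trace(state.Y.T @ state.L @ state.Y))
    Zp = state.P.T @ state.X
    rep = hp.beta * float(np.trace(Zp @ state.Mrep.Mrep @ Zp.T))
    return (
        float(np.sum(wc * fit_res))
        + prop
        + hp.rho * _l21(state.W)
        + float(np.sum(wc * dist_own + w0 * dists[:, 0]))
        + theta_term
        - rep
    )


def _centers_for(
    state: EDPCState, pair: DomainPair, hp: Hyperparams, pseudo: np.ndarray
) -> ClassCenters:
    """Membership-weighted blended centers for the given target labels.

    Weighted means are the stationary centers of the possibilistic
    objective; with all memberships at 1 (the ablated variant, or the first
    iteration) they reduce to plain means.
    """
    labels = np.concatenate([pair.source_labels, pseudo])
    w0 = state.Lam[:, 0]
    wc = state.Lam[np.arange(labels.size), labels]
    return class_centers(pair, pseudo, state.X, hp.delta, sample_weights=(w0, wc))


def _warm_start_labels(pair: DomainPair, X: np.ndarray) -> np.ndarray:
    """Nearest-source-class-mean pseudo-labels for the target block."""
    Xs, Xt = X[:, : pair.n], X[:, pair.n :]
    src = pair.source_labels
    means = np.stack(
        [Xs[:, src == c].mean(axis=1) for c in range(1, pair.C + 1)], axis=1
    )
    sq = (
        np.sum(Xt**2, axis=0)[:, None]
        + np.sum(means**2, axis=0)[None, :]
        - 2.0 * Xt.T @ means
    )
    return np.argmin(sq, axis=1) + 1


def fit(
    pair: DomainPair, hp: Hyperparams | None = None, fix_membership: bool = False
) -> EDPCState:
    """Fit EDPC by block-coordinate descent.

    The target is warm-started with a source-trained nearest-class-mean
    rule, the projection with the top-r principal directions of the pooled
    features, and the kNN graph is built once on the input features.  Each
    iteration cycles membership -> classifier -> labels -> projection,
    recomputing class centers and the repulsion matrix after label changes;
    the relaxed label and projection steps are kept only when they do not
    increase the objective.  Iteration stops when the objective change falls
    below ``eps_stop * (1 + |objective at start|)`` or at ``max_iter``.

    Set ``fix_membership=True`` to ablate the possibilistic weighting (all
    membership weights held at 1), the non-robust variant used as a control
    in the noise experiments.
    """
    if hp is None:
        hp = Hyperparams()
    X = pair.X
    if hp.kernel == "gaussian":
        sigma_k = hp.sigma_k or kernel_sigma_heuristic(X, pair.C)
        kernel_ref = X.copy()
        X = empirical_kernel_map(kernel_ref, X, sigma_k)
    else:
        kernel_ref = None
    center_vec = X.mean(axis=1)
    X = X - center_vec[:, None]

    d, N, C = X.shape[0], pair.N, pair.C
    r = hp.r if hp.r is not None else min(d, C + 1)
    if r >= N:
        raise ValueError(f"subspace dimension r={r} must be < N={N}")
    if r > d:
        raise ValueError(f"subspace dimension r={r} cannot exceed d={d}")

    pseudo = _warm_start_labels(pair, X)
    sigma_g = hp.sigma_graph or median_sigma(X)
    gr = knn_affinity(X, hp.k, sigma_g)
    L = laplacian(gr.M)

    U_, _, _ = linalg.svd(X, full_matrices=False)
    P = U_[:, :r]
    Y = np.zeros((N, C))
    Y[: pair.n] = pair.Ys
    Y[np.arange(pair.n, N), pseudo - 1] = 1.0

    state = EDPCState(
        P=P,
        W=np.zeros((r, C)),
        Ws=np.zeros((r, C)),
        Lam=np.ones((N, C + 1)),
        Y=Y,
        pseudo_labels=pseudo,
        centers=class_centers(pair, pseudo, X, hp.delta),
        Mrep=repulsion_matrix(
            np.concatenate([pair.source_labels, pseudo])
        ),
        L=L,
        X=X,
        center_vec=center_vec,
        hp=hp,
        n=pair.n,
        m=pair.m,
        C=C,
        kernel_ref=kernel_ref,
        fixed_membership=fix_membership,
    )

    theta0 = objective(state, pair, hp)
    state.objective_trace.append(theta0)
    eps_abs = hp.eps_stop * (1.0 + abs(theta0))
    accept_tol = 1e-9 * (1.0 + abs(theta0))

    for z in range(1, hp.max_iter + 1):
        if not fix_membership:
            state.Lam = update_membership(state, pair, hp)
            # guarded center refresh with the new membership weights
            centers_old = state.centers
            current = objective(state, pair, hp)
            state.centers = _centers_for(state, pair, hp, state.pseudo_labels)
            if objective(state, pair, hp) > current + accept_tol:
                state.centers = centers_old
        state.W, state.Ws = update_decision(state, pair, hp)
        current = objective(state, pair, hp)

        # guarded label step (relaxation + clamping is not exact descent)
        old = (state.Y, state.pseudo_labels, state.centers, state.Mrep)
        Y_new, pseudo_new, relaxed = update_labels(state, pair, hp)
        n_changed = 0
        accepted = False
        for attempt, pseudo_cand in enumerate((pseudo_new, None)):
            if pseudo_cand is None:
                # fallback: refine the current labels directly, skipping the
                # spectral proposal that was just rejected
                state.Y, state.pseudo_labels, state.centers, state.Mrep = old
                pseudo_cand = _icm_refine(state, hp, old[1])
                if np.array_equal(pseudo_cand, old[1]):
                    break
            Y_cand = np.zeros_like(state.Y)
            Y_cand[: pair.n] = pair.Ys
            Y_cand[np.arange(pair.n, N), pseudo_cand - 1] = 1.0
            state.Y, state.pseudo_labels = Y_cand, pseudo_cand
            state.centers = _centers_for(state, pair, hp, pseudo_cand)
            state.Mrep = repulsion_matrix(state.labels_all)
            cand = objective(state, pair, hp)
            if cand <= current + accept_tol:
                if attempt == 0:
                    state.relaxed_value = relaxed
                n_changed = int(np.sum(pseudo_cand != old[1]))
                current = cand
                accepted = True
                break
        if not accepted:
            state.Y, state.pseudo_labels, state.centers, state.Mrep = old

        # guarded projection step (polar projection is not exact descent)
        P_old = state.P
        P_new, _ = update_projection(state, pair, hp)
        state.P = P_new
        cand = objective(state, pair, hp)
        if cand <= current + accept_tol:
            current = cand
        else:
            state.P = P_old

        prev = state.objective_trace[-1]
        state.objective_trace.append(current)
        logger.info(
            "iter %d: obj=%.6g dObj=%.3g mean_w=%.3f relabeled=%d",
            z,
            current,
            current - prev,
            float(np.mean(_active_weights(state)[1])),
            n_changed,
        )
        if abs(current - prev) < eps_abs:
            state.converged = True
            break

    # final refresh: memberships and heads consistent with the final labels
    # (both are exact-descent steps, so the trace stays non-increasing)
    if not fix_membership:
        state.Lam = update_membership(state, pair, hp)
    state.W, state.Ws = update_decision(state, pair, hp)
    state.objective_trace.append(objective(state, pair, hp))

    if not state.converged:
        warnings.warn(
            f"EDPC did not converge within {hp.max_iter} iterations "
            f"(last |dObj|={abs(state.objective_trace[-1] - state.objective_trace[-2]):.3g})"
        )
    return state


def predict(
    state: EDPCState, X_new: np.ndarray, upsilon: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Fused prediction ``upsilon * source head + (1 - upsilon) * shared head``.

    Returns ``(labels, scores)`` with 1-based labels (argmax per row, ties
    resolved to the smallest class id) and the q x C fused score matrix.
    """
    if upsilon is None:
        upsilon = state.hp.upsilon
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if state.kernel_ref is not None:
        sigma_k = state.hp.sigma_k or kernel_sigma_heuristic(state.kernel_ref, state.C)
        X_new = empirical_kernel_map(state.kernel_ref, X_new, sigma_k)
    if X_new.shape[0] != state.center_vec.shape[0]:
        raise ValueError(
            f"feature dimension mismatch: model expects "
            f"{state.center_vec.shape[0]}, got {X_new.shape[0]}"
        )
    Z = state.P.T @ (X_new - state.center_vec[:, None])
    scores = upsilon * (Z.T @ state.Ws) + (1.0 - upsilon) * (Z.T @ state.W)
    labels = np.argmax(scores, axis=1) + 1
    return labels, scores
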