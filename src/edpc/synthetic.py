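"""Two-domain synthetic data with controllable covariate shift and noise.

The generator produces isotropic Gaussian class blobs shared by both
domains; the target copy is then rotated (in the plane of the first two
feature axes, about the blob centroid) and translated, so the marginal
feature distributions differ while the label space is shared.  Optional
corruption ops inject uniformly relabeled source samples and far-away
outlier samples, each returning an index mask so tests can check that the
model down-weights exactly the corrupted points.

The feature scale (class separation 12, within-class s.d. 2.0) is chosen so
squared point-to-center distances are of order 10^2, the scale at which the
default membership temperature theta = 400 yields informative weights.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .metrics import DomainPair

__all__ = [
    "SyntheticSpec",
    "make_domain_pair",
    "inject_label_noise",
    "inject_outliers",
    "NOISE_GRID",
]

# source-label corruption levels used in the robustness protocol
NOISE_GRID = (0.05, 0.15, 0.25, 0.30)


@dataclass
class SyntheticSpec:
    """Parameters of the two-domain blob generator."""

    d: int = 20
    C: int = 3
    n_per_class_source: int = 50
    n_per_class_target: int = 50
    class_separation: float = 12.0
    shift_rotation_deg: float = 30.0
    shift_translation: float = 2.0
    within_class_sd: float = 2.0
    outlier_fraction: float = 0.0
    outlier_scale: float = 3.0
    label_noise_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C < 2:
            raise ValueError("need at least two classes")
        if self.d < 2:
            raise ValueError("need at least two features for the rotation shift")
        if self.n_per_class_source < 1 or self.n_per_class_target < 1:
            raise ValueError("per-class sample counts must be positive")
        for name in ("outlier_fraction", "label_noise_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.within_class_sd <= 0:
            raise ValueError("within_class_sd must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def _class_means(spec: SyntheticSpec) -> np.ndarray:
    """Class means on scaled coordinate axes, pairwise class_separation apart."""
    mu = np.zeros((spec.d, spec.C))
    a = spec.class_separation / np.sqrt(2.0)
    for c in range(spec.C):
        mu[c % spec.d, c] = a
    return mu


def _rotation(d: int, deg: float) -> np.ndarray:
    """Rotation by ``deg`` degrees in the plane of the first two axes."""
    R = np.eye(d)
    t = np.deg2rad(deg)
    R[0, 0] = R[1, 1] = np.cos(t)
    R[0, 1] = -np.sin(t)
    R[1, 0] = np.sin(t)
    return R


def make_domain_pair(spec: SyntheticSpec) -> tuple[DomainPair, np.ndarray]:
    """Draw a source/target pair; returns ``(pair, true_target_labels)``.

    Target samples are drawn from the same class blobs as the source, then
    rotated about the blob centroid and translated along the diagonal unit
    direction; the true target labels are returned for evaluation only.
    Corruption (label noise on the source, outliers on both domains) is
    applied when the corresponding spec fractions are positive.
    """
    rng = np.random.default_rng(spec.seed)
    mu = _class_means(spec)
    n_s, n_t = spec.n_per_class_source, spec.n_per_class_target

    ys = np.repeat(np.arange(1, spec.C + 1), n_s)
    yt = np.repeat(np.arange(1, spec.C + 1), n_t)
    Xs = mu[:, ys - 1] + spec.within_class_sd * rng.standard_normal((spec.d, ys.size))
    Xt_raw = mu[:, yt - 1] + spec.within_class_sd * rng.standard_normal((spec.d, yt.size))

    center = mu.mean(axis=1, keepdims=True)
    R = _rotation(spec.d, spec.shift_rotation_deg)
    shift_dir = np.ones(spec.d) / np.sqrt(spec.d)
    Xt = R @ (Xt_raw - center) + center + (
        spec.shift_translation * shift_dir
    )[:, None]

    Ys = np.zeros((ys.size, spec.C))
    Ys[np.arange(ys.size), ys - 1] = 1.0

    if spec.label_noise_fraction > 0:
        Ys, _ = inject_label_noise(
            Ys, spec.label_noise_fraction, seed=int(rng.integers(2**31))
        )
    if spec.outlier_fraction > 0:
        Xs, _ = inject_outliers(
            Xs, spec.outlier_fraction, spec.outlier_scale,
            seed=int(rng.integers(2**31)),
        )
        Xt, _ = inject_outliers(
            Xt, spec.outlier_fraction, spec.outlier_scale,
            seed=int(rng.integers(2**31)),
        )
    return DomainPair(Xs=Xs, Ys=Ys, Xt=Xt), yt


def inject_label_noise(
    Ys: np.ndarray, fraction: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Replace ``round(fraction * n)`` one-hot rows with a *different* class.

    Returns ``(corrupted_Ys, mask)`` where ``mask[i]`` flags corrupted rows.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    Ys = np.asarray(Ys, dtype=float)
    n, C = Ys.shape
    rng = np.random.default_rng(seed)
    n_noise = int(round(fraction * n))
    mask = np.zeros(n, dtype=bool)
    out = Ys.copy()
    idx = rng.choice(n, size=n_noise, replace=False)
    for i in idx:
        true_c = int(np.argmax(Ys[i]))
        wrong = [c for c in range(C) if c != true_c]
        new_c = int(rng.choice(wrong))
        out[i] = 0.0
        out[i, new_c] = 1.0
        mask[i] = True
    return out, mask


def inject_outliers(
    X: np.ndarray, fraction: float, scale: float = 3.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Replace a fraction of samples with points at ``scale`` x data radius.

    Selected columns are replaced by ``center + scale * radius * u`` for a
    random unit direction ``u``, where the radius is the largest distance of
    any sample from the data centroid.  Returns ``(X_out, mask)``.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    X = np.asarray(X, dtype=float)
    d, n = X.shape
    rng = np.random.default_rng(seed)
    n_out = int(round(fraction * n))
    mask = np.zeros(n, dtype=bool)
    out = X.copy()
    if n_out == 0:
        return out, mask
    center = X.mean(axis=1)
    radius = float(np.max(np.linalg.norm(X - center[:, None], axis=0)))
    idx = rng.choice(n, size=n_out, replace=False)
    for i in idx:
        u = rng.standard_normal(d)
        u /= np.linalg.norm(u)
        out[:, i] = center + scale * radius * u
        mask[i] = True
    return out, mask
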