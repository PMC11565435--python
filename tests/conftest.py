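"""Shared fixtures: small domain pairs, fitted states, and baselines."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from edpc import Hyperparams, SyntheticSpec, fit, make_domain_pair

N_SEEDS = 10  # seeds used for seed-averaged properties


def default_pair(seed: int, **overrides):
    """The study-condition generator: shifted 3-class pair, N = 300, d = 20."""
    return make_domain_pair(SyntheticSpec(seed=seed, **overrides))


def quiet_fit(pair, hp=None, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit(pair, hp, **kwargs)


def ridge_target_accuracy(pair, yt) -> float:
    """Source-only ridge baseline evaluated on the target domain."""
    from sklearn.linear_model import RidgeClassifier

    clf = RidgeClassifier().fit(pair.Xs.T, pair.source_labels)
    return float(np.mean(clf.predict(pair.Xt.T) == yt))


@pytest.fixture(scope="session")
def small_pair():
    """A compact 2-class pair for update-level tests (fast to fit)."""
    spec = SyntheticSpec(
        d=5, C=2, n_per_class_source=12, n_per_class_target=12, seed=7,
        class_separation=8.0, within_class_sd=1.5,
    )
    return make_domain_pair(spec)


@pytest.fixture(scope="session")
def small_state(small_pair):
    """A state mid-optimization on the small pair (2 iterations)."""
    pair, _ = small_pair
    hp = Hyperparams(max_iter=2)
    return quiet_fit(pair, hp), hp


@pytest.fixture(scope="session")
def default_fits():
    """Fitted states + truth + pairs for the study-condition seeds 0..9."""
    out = []
    for seed in range(N_SEEDS):
        pair, yt = default_pair(seed)
        out.append((pair, yt, quiet_fit(pair)))
    return out
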