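"""Reproducible classifier experiments on simulated repertoire profiles."""

from __future__ import annotations

import numpy as np

from .clonality import compute_profile, feature_matrix, train_knn
from .simulate import simulate_profile


def knn_profile_experiment(
    seed: int = 1,
    n_one_clone: int = 30,
    n_two_clone: int = 30,
    n_polyclonal: int = 30,
    k: int = 3,
    train_size: float = 0.25,
) -> dict:
    """Scaled-down clonality-classifier experiment.

    Simulates labelled repertoire profiles (dominant-clone and
    two-dominant-clone samples vs polyclonal), computes the per-sample
    features (log10 MAX_DIFF, top-clone percentage), performs a stratified
    random split with a small training fraction, and fits the KNN
    classifier.  Returns the accuracy/CV report plus the problem size.
    """
    rng = np.random.default_rng(seed)
    profiles, labels = [], []
    for kind, n, label in (
        ("one_clone", n_one_clone, "clonal"),
        ("two_clone", n_two_clone, "clonal"),
        ("polyclonal", n_polyclonal, "polyclonal"),
    ):
        for i in range(n):
            pcts = 100 * simulate_profile(kind, rng_seed=rng)
            profiles.append(compute_profile(pcts, sample_id=f"{kind}{i}"))
            labels.append(label)
    _, report = train_knn(
        feature_matrix(profiles), labels, k=k, seed=seed, train_size=train_size
    )
    report["n_profiles"] = len(profiles)
    return report
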