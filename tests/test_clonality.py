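"""MAX_DIFF profiles, KNN classification, and group statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ighrep.clonality import (
    classify_sample,
    compute_profile,
    concordance_pct,
    confusion_metrics,
    feature_matrix,
    group_stats,
    mann_whitney_u,
    train_knn,
)
from ighrep.experiments import knn_profile_experiment
from ighrep.simulate import simulate_profile


@pytest.mark.parametrize("pcts, ratios, max_diff, position", [
    ([50, 25, 12.5], [2, 2], 2.0, 1),            # tie -> earliest position
    ([60, 5, 4, 1], [12, 1.25, 4], 12.0, 1),
    ([40, 30, 2], [4 / 3, 15], 15.0, 2),
])
def test_profile_ratio_enumeration(pcts, ratios, max_diff, position):
    p = compute_profile(pcts)
    assert p.ratios == pytest.approx(ratios)
    assert p.max_diff == pytest.approx(max_diff)
    assert p.max_diff_position == position


def test_profile_filters_below_min_pct():
    p = compute_profile([60, 5, 4, 1, 0.05])
    assert len(p.clone_pcts) == 4  # 0.05% clone removed before ratios


def test_single_clone_profile_sentinel():
    p = compute_profile([100.0])
    assert math.isinf(p.max_diff)
    assert p.max_diff_position == 1


def test_all_filtered_profile_is_empty():
    p = compute_profile([0.05, 0.01])
    assert p.empty


@settings(deadline=None, max_examples=60)
@given(
    r=st.floats(min_value=1.01, max_value=10, allow_nan=False),
    n=st.integers(min_value=3, max_value=10),
)
def test_geometric_profile_closed_form(r, n):
    """A geometric abundance profile with ratio r has MAX_DIFF exactly r."""
    pcts = [100 * r ** -i for i in range(n)]
    p = compute_profile(pcts, min_pct=0.0)
    assert p.max_diff == pytest.approx(r)


@settings(deadline=None, max_examples=40)
@given(
    scale=st.floats(min_value=0.01, max_value=100),
    seed=st.integers(min_value=0, max_value=1000),
)
def test_max_diff_scale_invariant(scale, seed):
    rng = np.random.default_rng(seed)
    pcts = np.sort(rng.uniform(1, 50, size=6))[::-1]
    a = compute_profile(pcts, min_pct=0.0)
    b = compute_profile(pcts * scale, min_pct=0.0)
    assert b.max_diff == pytest.approx(a.max_diff)
    assert b.max_diff_position == a.max_diff_position


def _labelled_profiles(n_per=20, seed=0):
    rng = np.random.default_rng(seed)
    profiles, labels = [], []
    for kind, label in (("one_clone", "clonal"), ("polyclonal", "polyclonal")):
        for i in range(n_per):
            profiles.append(compute_profile(100 * simulate_profile(kind, rng_seed=rng)))
            labels.append(label)
    return profiles, labels


def test_knn_separable_features_reach_perfect_test_accuracy():
    profiles, labels = _labelled_profiles(n_per=30)
    _, report = train_knn(feature_matrix(profiles), labels, seed=0)
    assert report["test_accuracy"] == 1.0
    assert report["cv_f1_macro_mean"] >= 0.95


def test_knn_scaled_experiment_report_fields():
    report = knn_profile_experiment(seed=3)
    assert report["n_profiles"] == 90
    assert report["k"] == 3
    assert 0.0 <= report["test_accuracy"] <= 1.0


def test_knn_one_class_errors():
    with pytest.raises(ValueError, match="two classes"):
        train_knn(np.zeros((10, 2)), ["clonal"] * 10)


def test_knn_k_exceeding_samples_errors():
    x = np.arange(8, dtype=float).reshape(4, 2)
    with pytest.raises(ValueError, match="exceeds"):
        train_knn(x, ["a", "a", "b", "b"], k=9)


def test_permuted_labels_drop_to_chance():
    profiles, labels = _labelled_profiles(n_per=30)
    rng = np.random.default_rng(1)
    shuffled = list(labels)
    rng.shuffle(shuffled)
    _, report = train_knn(feature_matrix(profiles), shuffled, seed=0, train_size=0.5)
    assert report["test_accuracy"] <= 0.75  # near the 0.5 class prior


def test_classify_simulated_kinds():
    profiles, labels = _labelled_profiles(n_per=30, seed=5)
    model, _ = train_knn(feature_matrix(profiles), labels, seed=0)
    for kind, expected_n in (("one_clone", 1), ("two_clone", 2), ("polyclonal", 0)):
        for seed in range(900, 910):
            p = compute_profile(100 * simulate_profile(kind, rng_seed=seed))
            call = classify_sample(p, model)
            if kind == "polyclonal":
                assert call.label == "polyclonal"
                assert call.clonal_ids == []
            else:
                assert call.label == f"{expected_n}CLONE"
                assert len(call.clonal_ids) == expected_n


def test_classify_single_clone_profile():
    profiles, labels = _labelled_profiles(n_per=20)
    model, _ = train_knn(feature_matrix(profiles), labels, seed=0)
    call = classify_sample(compute_profile([100.0]), model)
    assert call.label == "1CLONE"


def test_classify_empty_profile_unclassifiable():
    profiles, labels = _labelled_profiles(n_per=20)
    model, _ = train_knn(feature_matrix(profiles), labels, seed=0)
    call = classify_sample(compute_profile([0.01]), model)
    assert call.label == "unclassifiable"


def _oracle_mann_whitney(x, y):
    """Brute-force two-sided Mann-Whitney p by direct pair counting over
    every regrouping of the pooled values."""
    def u_stat(a, b):
        return sum(
            1.0 if xi > yi else 0.5 if xi == yi else 0.0 for xi in a for yi in b
        )

    pooled = list(x) + list(y)
    mu = len(x) * len(y) / 2
    observed = abs(u_stat(x, y) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), len(x)):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(a, b) - mu) >= observed - 1e-12:
            hits += 1
    return hits / total


def test_mann_whitney_worked_example():
    u, p = mann_whitney_u([8, 9, 10], [1, 2, 2])
    assert u == 9.0
    assert p == pytest.approx(_oracle_mann_whitney([8, 9, 10], [1, 2, 2]))


@pytest.mark.parametrize("seed", range(8))
def test_mann_whitney_matches_permutation_oracle(seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 10, size=rng.integers(3, 5)).tolist()
    y = rng.integers(0, 10, size=rng.integers(3, 5)).tolist()
    u, p = mann_whitney_u(x, y)
    assert p == pytest.approx(_oracle_mann_whitney(x, y))


def test_group_stats_identical_groups():
    groups = {"a": [5, 6, 7, 8], "b": [5, 6, 7, 8]}
    summary, pairwise = group_stats(groups)
    assert pairwise["p_bonferroni"].iloc[0] == 1.0


def test_group_stats_summary_and_folds():
    groups = {
        "polyclonal": [2.0, 2.1, 1.9],
        "one_clone": [200.0, 210.0, 190.0],
        "multi": [100.0, 90.0, 110.0],
    }
    summary, pairwise = group_stats(groups, reference="polyclonal")
    row = summary.set_index("group")
    assert row.loc["one_clone", "fold_vs_reference"] == pytest.approx(100.0)
    assert row.loc["one_clone", "maximum_max_diff"] == 210.0
    assert len(pairwise) == 3  # Bonferroni m = 3 pairwise comparisons
    assert (pairwise["p_bonferroni"] >= pairwise["p_value"] - 1e-12).all()


def test_group_stats_excludes_small_groups():
    groups = {"a": [1, 2, 3], "b": [4, 5, 6], "tiny": [9]}
    with pytest.warns(UserWarning, match="tiny"):
        summary, _ = group_stats(groups)
    assert set(summary["group"]) == {"a", "b"}


@pytest.mark.parametrize("kwargs, sens, spec", [
    ({"tn": 306, "fp": 8, "tp": 10, "fn": 0}, 100.0, 97.45),
    ({"tp": 7, "fn": 0}, 100.0, None),
    ({}, None, None),
])
def test_confusion_metrics(kwargs, sens, spec):
    out = confusion_metrics(**kwargs)
    assert out["sensitivity"] == sens
    assert out["specificity"] == spec


def test_concordance_formatting():
    assert concordance_pct(329, 344) == 95.64
    assert concordance_pct(293, 333) == 87.99
    assert concordance_pct(341, 344, decimals=1) == 99.1
    with pytest.raises(ValueError):
        concordance_pct(1, 0)
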