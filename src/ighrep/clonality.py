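"""Repertoire structure: MAX_DIFF, KNN classification, group statistics.

A sample's clones are ordered by abundance; the ratio of each clone's
percentage to the next one's is computed, and the maximum of these
consecutive ratios is the per-sample clonal cut-off statistic (MAX_DIFF).
A clonally expanded repertoire shows a large gap somewhere in the ranking
(MAX_DIFF well above the polyclonal range), and the 1-based position N of
that gap is the number of clonal rearrangements: the sample is tagged
"NCLONE", clones ranked 1..N are clonal and the rest subclonal.  Healthy
polyclonal repertoires have near-flat profiles and small MAX_DIFF.

The clonal-vs-polyclonal decision itself is a KNN classification (k = 3 by
default) on standardized per-sample features — log10(MAX_DIFF) and the
top-clone percentage — trained on labelled profiles.  Group differences in
MAX_DIFF are compared with two-sided Mann-Whitney U tests under Bonferroni
correction.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

DEFAULT_MIN_PCT = 0.1
DEFAULT_K = 3
#: cap applied to MAX_DIFF before log10 so the single-clone sentinel
#: (infinite MAX_DIFF) maps to a finite feature value
MAX_DIFF_FEATURE_CAP = 1e4


@dataclass
class RepertoireProfile:
    """Ordered clone-abundance profile of one sample."""

    sample_id: str
    clone_ids: list[str]
    clone_pcts: np.ndarray  # descending percentages, clones < min_pct removed
    ratios: np.ndarray  # consecutive ratios pct[i]/pct[i+1]
    max_diff: float  # max ratio; math.inf sentinel for single-clone samples
    max_diff_position: int  # 1-based rank at which the maximum occurs

    @property
    def empty(self) -> bool:
        return len(self.clone_pcts) == 0


@dataclass
class ClonalityCall:
    sample_id: str
    label: str  # "polyclonal", "NCLONE" (e.g. "2CLONE") or "unclassifiable"
    n_clonal: int
    clonal_ids: list[str]
    subclonal_ids: list[str]
    max_diff: float = math.nan
    knn_neighbors: int = DEFAULT_K
    feature_vector: tuple[float, float] | None = None
    near_threshold: bool = False


def compute_profile(
    rearrs_or_pcts,
    min_pct: float = DEFAULT_MIN_PCT,
    sample_id: str = "sample",
    clone_ids: list[str] | None = None,
) -> RepertoireProfile:
    """Build the abundance profile: drop clones below ``min_pct`` percent,
    sort descending, compute consecutive ratios and MAX_DIFF (ties in the
    maximum ratio resolve to the earliest, most abundant position)."""
    if hasattr(rearrs_or_pcts[0] if len(rearrs_or_pcts) else None, "clonal_pct"):
        pcts = np.array([r.clonal_pct for r in rearrs_or_pcts], dtype=float)
        ids = [r.name for r in rearrs_or_pcts]
    else:
        pcts = np.asarray(rearrs_or_pcts, dtype=float)
        ids = clone_ids or [f"clone{i + 1}" for i in range(len(pcts))]
    order = np.argsort(-pcts, kind="stable")
    pcts = pcts[order]
    ids = [ids[i] for i in order]
    keep = pcts >= min_pct
    pcts = pcts[keep]
    ids = [i for i, k in zip(ids, keep) if k]
    if len(pcts) == 0:
        return RepertoireProfile(sample_id, [], pcts, np.array([]), math.nan, 0)
    if len(pcts) == 1:
        return RepertoireProfile(sample_id, ids, pcts, np.array([]), math.inf, 1)
    ratios = pcts[:-1] / pcts[1:]
    pos = int(np.argmax(ratios))  # first maximal ratio
    return RepertoireProfile(sample_id, ids, pcts, ratios, float(ratios[pos]), pos + 1)


def profile_features(profile: RepertoireProfile) -> tuple[float, float]:
    """Per-sample KNN feature vector: (log10 MAX_DIFF, top-clone %)."""
    if profile.empty:
        raise ValueError(f"empty profile for {profile.sample_id}")
    md = min(profile.max_diff, MAX_DIFF_FEATURE_CAP)
    return (math.log10(md), float(profile.clone_pcts[0]))


def feature_matrix(profiles: list[RepertoireProfile]) -> np.ndarray:
    return np.array([profile_features(p) for p in profiles])


def train_knn(
    features: np.ndarray,
    labels,
    k: int = DEFAULT_K,
    seed: int = 0,
    train_size: float = 0.25,
    n_folds: int = 10,
) -> tuple[Pipeline, dict]:
    """Fit the clonality classifier and report its accuracy.

    Euclidean KNN on standardized features; stratified random train/test
    split (a small training fraction, the rest held out for testing) plus
    stratified ``n_folds``-fold cross-validated F1-micro / F1-macro.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training set must contain at least two classes")
    if k > len(labels):
        raise ValueError(f"k={k} exceeds the number of samples ({len(labels)})")

    x_train, x_test, y_train, y_test = train_test_split(
        features, labels, train_size=train_size, stratify=labels, random_state=seed
    )
    if k > len(y_train):
        raise ValueError(f"k={k} exceeds the training-set size ({len(y_train)})")
    model = Pipeline(
        [("scale", StandardScaler()), ("knn", KNeighborsClassifier(n_neighbors=k))]
    )
    model.fit(x_train, y_train)
    report = {
        "k": k,
        "n_train": len(y_train),
        "n_test": len(y_test),
        "train_accuracy": float(accuracy_score(y_train, model.predict(x_train))),
        "test_accuracy": float(accuracy_score(y_test, model.predict(x_test))),
    }
    n_folds_eff = min(n_folds, min(np.bincount(pd.factorize(labels)[0])))
    if n_folds_eff >= 2:
        cv = StratifiedKFold(n_splits=n_folds_eff, shuffle=True, random_state=seed)
        fresh = Pipeline(
            [("scale", StandardScaler()), ("knn", KNeighborsClassifier(n_neighbors=k))]
        )
        for metric in ("f1_micro", "f1_macro"):
            scores = cross_val_score(fresh, features, labels, cv=cv, scoring=metric)
            report[f"cv_{metric}_mean"] = float(scores.mean())
            report[f"cv_{metric}_sd"] = float(scores.std())
    return model, report


def classify_sample(profile: RepertoireProfile, model) -> ClonalityCall:
    """Tag one sample polyclonal or NCLONE from its fitted classifier.

    For clonal calls N is the 1-based position of the maximum consecutive
    ratio; a single-clone profile (infinite MAX_DIFF sentinel) is 1CLONE.
    Profiles whose MAX_DIFF falls between the polyclonal maximum (3.77)
    and the clonal minimum (8.19) seen in validation are flagged
    near-threshold.
    """
    if profile.empty:
        return ClonalityCall(profile.sample_id, "unclassifiable", 0, [], [])
    feats = profile_features(profile)
    raw = str(model.predict(np.array([feats]))[0])
    near = 3.77 < profile.max_diff < 8.19
    if raw == "polyclonal":
        return ClonalityCall(
            profile.sample_id, "polyclonal", 0, [], list(profile.clone_ids),
            max_diff=profile.max_diff, feature_vector=feats, near_threshold=near,
        )
    n = profile.max_diff_position
    return ClonalityCall(
        profile.sample_id,
        f"{n}CLONE",
        n,
        list(profile.clone_ids[:n]),
        list(profile.clone_ids[n:]),
        max_diff=profile.max_diff,
        feature_vector=feats,
        near_threshold=near,
    )


def mann_whitney_u(x, y, exact_max_n: int = 20) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact permutation enumeration when the pooled size is at most
    ``exact_max_n`` (correct under ties); normal approximation with tie
    correction otherwise.  Returns (U statistic for x, p value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if n1 + n2 <= exact_max_n:
        mu = n1 * n2 / 2
        observed = abs(u1 - mu)
        count = total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            r = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
            total += 1
            if abs(r - mu) >= observed - 1e-12:
                count += 1
        return u1, count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u1, float(res.pvalue)


def fold_change(avg: float, reference_avg: float) -> float:
    """Fold-difference of a group's average MAX_DIFF over a reference."""
    if reference_avg == 0:
        raise ValueError("reference average is zero")
    return avg / reference_avg


def group_stats(
    groups: dict[str, list[float]],
    reference: str | None = None,
    min_group_size: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average/max/min MAX_DIFF per group, fold differences vs a reference
    group, and Bonferroni-corrected pairwise Mann-Whitney U tests.

    Groups with fewer than ``min_group_size`` samples are excluded with a
    warning.  The reference for fold differences defaults to the group
    with the smallest average (the polyclonal-like group).
    """
    usable = {}
    for name, vals in groups.items():
        if len(vals) < min_group_size:
            warnings.warn(f"group {name!r} has {len(vals)} < {min_group_size} samples; excluded")
            continue
        usable[name] = np.asarray(vals, dtype=float)
    if len(usable) < 2:
        raise ValueError("need at least two groups with enough samples")

    avgs = {name: float(v.mean()) for name, v in usable.items()}
    ref = reference if reference is not None else min(avgs, key=avgs.get)
    summary = pd.DataFrame(
        [
            {
                "group": name,
                "n": len(v),
                "average_max_diff": round(avgs[name], 2),
                "maximum_max_diff": round(float(v.max()), 2),
                "minimum_max_diff": round(float(v.min()), 2),
                "fold_vs_reference": round(fold_change(avgs[name], avgs[ref]), 2),
            }
            for name, v in usable.items()
        ],
        columns=[
            "group", "n", "average_max_diff", "maximum_max_diff",
            "minimum_max_diff", "fold_vs_reference",
        ],
    )

    pairs = list(itertools.combinations(sorted(usable), 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        u, p = mann_whitney_u(usable[a], usable[b])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "u_statistic": u,
                "p_value": p,
                "p_bonferroni": min(1.0, p * m),
            }
        )
    pairwise = pd.DataFrame(
        rows, columns=["group_a", "group_b", "u_statistic", "p_value", "p_bonferroni"]
    )
    return summary, pairwise


def concordance_pct(agreeing: int, total: int, decimals: int = 2) -> float:
    """Report-formatter percentage: 100 x agreeing / total, rounded."""
    if total == 0:
        raise ValueError("zero denominator")
    return float(round(100 * Fraction(agreeing, total), decimals))


def confusion_metrics(
    tp: int = 0, fp: int = 0, tn: int = 0, fn: int = 0
) -> dict[str, float | None]:
    """Sensitivity and specificity in percent (exact rational arithmetic,
    2-decimal rounding); None where the denominator is zero."""
    specificity = (
        float(round(100 * Fraction(tn, tn + fp), 2)) if (tn + fp) > 0 else None
    )
    sensitivity = (
        float(round(100 * Fraction(tp, tp + fn), 2)) if (tp + fn) > 0 else None
    )
    return {"sensitivity": sensitivity, "specificity": specificity}


def profile_frame(profiles: list[RepertoireProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for rank, (cid, pct) in enumerate(zip(p.clone_ids, p.clone_pcts), start=1):
            rows.append(
                {
                    "sample": p.sample_id,
                    "rank": rank,
                    "clone_id": cid,
                    "clone_pct": round(float(pct), 6),
                    "ratio_to_next": round(float(p.ratios[rank - 1]), 6)
                    if rank <= len(p.ratios)
                    else "",
                }
            )
    return pd.DataFrame(rows, columns=["sample", "rank", "clone_id", "clone_pct", "ratio_to_next"])


def calls_frame(calls: list[ClonalityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": c.sample_id,
                "label": c.label,
                "n_clonal": c.n_clonal,
                "max_diff": "" if math.isnan(c.max_diff) else round(c.max_diff, 4),
                "log10_max_diff": round(c.feature_vector[0], 4) if c.feature_vector else "",
                "top_clone_pct": round(c.feature_vector[1], 4) if c.feature_vector else "",
                "near_threshold": c.near_threshold,
                "clonal_ids": ";".join(c.clonal_ids),
            }
            for c in calls
        ],
        columns=[
            "sample", "label", "n_clonal", "max_diff", "log10_max_diff",
            "top_clone_pct", "near_threshold", "clonal_ids",
        ],
    )
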