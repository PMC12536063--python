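"""Artifact collapse, gene-level summary, and sample QC."""

import random

import numpy as np
import pytest

from ighrep.annotate import Annotation
from ighrep.artifacts import (
    apply_artifact_filter,
    merge_by_identity,
    merge_low_support,
    sample_qc,
    summarize_gene_level,
)
from ighrep.consensus import Rearrangement


def _mk(
    v="IGHV1-69*09",
    j="IGHJ4*02",
    consensus="",
    reads=100,
    support=None,
    cdr3="CARW",
) -> Rearrangement:
    r = Rearrangement(
        v, j, consensus, "", (len(consensus), len(consensus)),
        read_count=reads,
        fragment_support=dict(support or {"FR1": reads // 3, "FR2": reads // 3, "FR3": reads - 2 * (reads // 3)}),
        depth_profile=np.full(max(len(consensus), 1), reads),
    )
    r.annotation = Annotation(identity_pct=100.0, mutational_status="UM", cdr3_aa=cdr3)
    return r


def _mutate(seq: str, n: int, seed: int = 0) -> str:
    rng = random.Random(seed)
    chars = list(seq)
    for p in rng.sample(range(len(seq)), n):
        chars[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[p]]
    return "".join(chars)


@pytest.fixture
def base_consensus(db):
    from ighrep.simulate import simulate_rearrangement

    return simulate_rearrangement(db, rng_seed=8).true_sequence


def test_high_identity_siblings_merge(base_consensus):
    big = _mk(v="IGHV1-69*09", consensus=base_consensus, reads=900)
    # sibling allele of the same gene, consensus ~97% identical, same CDR3
    small = _mk(v="IGHV1-69*06", consensus=_mutate(base_consensus, 10), reads=100)
    merged, events = merge_by_identity([big, small])
    assert len(merged) == 1
    assert merged[0].read_count == 1000
    assert merged[0].v_allele == "IGHV1-69*09"  # absorber keeps its identity
    assert events[0].rule == "allele_identity95"
    assert events[0].identity_at_merge >= 95
    assert "IGHV1-69*06" in merged[0].merged_alleles


def test_cross_gene_merge_uses_second_pass(base_consensus):
    big = _mk(v="IGHV1-69*09", consensus=base_consensus, reads=900)
    other = _mk(v="IGHV3-7*04", consensus=_mutate(base_consensus, 8), reads=50)
    merged, events = merge_by_identity([big, other])
    assert len(merged) == 1
    assert events[0].rule == "gene_identity95"


def test_low_identity_not_merged(base_consensus):
    big = _mk(v="IGHV1-69*09", consensus=base_consensus, reads=900)
    far = _mk(v="IGHV1-69*06", consensus=_mutate(base_consensus, 40, seed=2), reads=100)
    merged, events = merge_by_identity([big, far])
    assert len(merged) == 2
    assert events == []


def test_merge_order_independent(base_consensus):
    def build():
        return [
            _mk(v="IGHV1-69*09", consensus=base_consensus, reads=900),
            _mk(v="IGHV1-69*06", consensus=_mutate(base_consensus, 10), reads=100),
            _mk(v="IGHV3-7*04", consensus=_mutate(base_consensus, 8), reads=50),
        ]
    forward, _ = merge_by_identity(build())
    backward, _ = merge_by_identity(build()[::-1])
    assert {(r.name, r.read_count) for r in forward} == {
        (r.name, r.read_count) for r in backward
    }


def test_fr3_dominant_absorbed_into_same_family_major(base_consensus):
    major = _mk(v="IGHV1-69*09", consensus=base_consensus, reads=900, cdr3="CARXW")
    minor = _mk(
        v="IGHV1-2*04", consensus=_mutate(base_consensus, 40, seed=3), reads=100,
        support={"FR3": 95, "FR1": 5}, cdr3="CARXW",
    )
    merged, events = merge_low_support([major, minor])
    assert len(merged) == 1
    assert merged[0].read_count == 1000
    assert events[0].rule == "fr3_dominant"


def test_balanced_support_untouched(base_consensus):
    major = _mk(consensus=base_consensus, reads=900, cdr3="CARXW")
    minor = _mk(
        v="IGHV1-2*04", consensus=_mutate(base_consensus, 40, seed=3), reads=100,
        support={"FR1": 10, "FR2": 10, "FR3": 80}, cdr3="CARXW",
    )
    merged, events = merge_low_support([major, minor])
    assert len(merged) == 2 and events == []


def test_single_fragment_without_major_flagged(base_consensus):
    lonely = _mk(consensus=base_consensus, reads=50, support={"FR2": 50}, cdr3="CUNIQW")
    merged, events = merge_low_support([lonely])
    assert len(merged) == 1 and events == []
    assert "low-support" in merged[0].flags


def test_shadow_clone_collapses_to_one(base_consensus):
    """A 96%-identity shadow sharing the CDR3 — the false-positive
    mechanism — is absorbed, leaving exactly one rearrangement."""
    true_clone = _mk(v="IGHV1-69*09", consensus=base_consensus, reads=950)
    shadow = _mk(
        v="IGHV1-69*06",
        consensus=_mutate(base_consensus, round(0.04 * len(base_consensus))),
        reads=50,
    )
    merged, events = apply_artifact_filter([true_clone, shadow])
    assert len(merged) == 1
    assert merged[0].read_count == 1000


def test_filter_conserves_reads_and_is_idempotent(base_consensus):
    rearrs = [
        _mk(v="IGHV1-69*09", consensus=base_consensus, reads=900),
        _mk(v="IGHV1-69*06", consensus=_mutate(base_consensus, 10), reads=80),
        _mk(v="IGHV4-34*01", consensus=_mutate(base_consensus, 60, seed=5), reads=40, cdr3="COTHERW"),
    ]
    total_before = sum(r.read_count for r in rearrs)
    once, _ = apply_artifact_filter(rearrs)
    assert sum(r.read_count for r in once) == total_before
    twice, events2 = apply_artifact_filter(once)
    assert events2 == []
    assert {(r.name, r.read_count) for r in twice} == {(r.name, r.read_count) for r in once}


def test_gene_level_summary(base_consensus):
    big = _mk(v="IGHV1-69*09", consensus=base_consensus, reads=900)
    small = _mk(v="IGHV1-69*06", consensus=_mutate(base_consensus, 10), reads=100)
    merged, _ = merge_by_identity([big, small])
    report = summarize_gene_level(merged)
    assert len(report) == 1
    row = report.iloc[0]
    assert row["v_gene"] == "IGHV1-69"
    assert set(row["v_alleles"].split(";")) == {"IGHV1-69*09", "IGHV1-69*06"}
    assert report["clonal_pct"].sum() == pytest.approx(100.0, abs=1e-6)


def test_gene_level_summary_empty():
    assert summarize_gene_level([]).empty


@pytest.mark.parametrize("track, kwargs, ok", [
    ("clonal", {"major_reads": 1001}, True),
    ("clonal", {"major_reads": 1000}, False),   # strict inequality
    ("clonal", {"major_reads": None}, False),
    ("polyclonal", {"trimmed_reads": 1000}, True),
    ("polyclonal", {"trimmed_reads": 999}, False),
])
def test_sample_qc(track, kwargs, ok):
    passed, reason = sample_qc(track, **kwargs)
    assert passed is ok
    assert ok == (reason == "")
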