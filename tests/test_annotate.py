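"""V identity, mutational status, CDR3 extraction, and D inference."""

import numpy as np
import pytest

from ighrep.annotate import (
    annotate_rearrangement,
    call_mutational_status,
    extract_cdr3,
    infer_d,
    v_identity,
)
from ighrep.consensus import Rearrangement
from ighrep.simulate import simulate_rearrangement


def _rearr_from_truth(rr) -> Rearrangement:
    """Wrap a simulated truth sequence as if it were a perfect consensus."""
    v_len = len(rr.v_mutated)
    return Rearrangement(
        rr.v_name, rr.j_name, rr.true_sequence, rr.true_junction,
        (v_len, v_len + len(rr.true_junction)),
        read_count=100, fragment_support={"FR1": 100},
        depth_profile=np.ones(len(rr.true_sequence), dtype=int),
    )


def test_zero_shm_identity_100(db):
    rr = simulate_rearrangement(db, shm_rate=0.0, rng_seed=2)
    identity, mutations, flags = v_identity(_rearr_from_truth(rr), db)
    assert identity == 100.0
    assert mutations == []
    assert flags == []


def test_identity_by_direct_substitution_count(db):
    """k substitutions over the full-length V alignment give exactly
    100*(L-k)/L identity, and the mutation list names each one."""
    rr = simulate_rearrangement(db, shm_rate=0.0, rng_seed=3)
    v = list(rr.v_germline)
    positions = [10, 50, 90, 130, 170, 210]
    for p in positions:
        v[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[v[p]]
    mutated = "".join(v) + rr.true_junction + db[rr.j_name].sequence
    rearr = _rearr_from_truth(rr)
    rearr.consensus = mutated
    identity, mutations, _ = v_identity(rearr, db)
    L = len(rr.v_germline)
    assert identity == pytest.approx(100 * (L - 6) / L)
    assert [m[0] for m in mutations] == positions


def test_shm_recovery_within_one_point(db, shm_run):
    """Measured identity tracks 100*(1 - shm_rate) within +-1 point when
    the whole V region is covered."""
    sample, result = shm_run
    truth = sample.rearrangements[0]
    top = max(result.rearrangements, key=lambda r: r.read_count)
    identity, _, _ = v_identity(top, db)
    assert identity == pytest.approx(100 * (1 - truth.shm_rate), abs=1.0)


@pytest.mark.parametrize("identity, status", [
    (98.0, "UM"),         # the 98% boundary itself is unmutated
    (100.0, "UM"),
    (97.92, "borderline"),
    (97.59, "borderline"),
    (97.57, "borderline"),
    (96.99, "MM"),
    (90.0, "MM"),
])
def test_mutational_status_calls(identity, status):
    assert call_mutational_status(identity) == status


def test_status_monotone_in_identity():
    rank = {"MM": 0, "borderline": 1, "UM": 2}
    grid = [call_mutational_status(x) for x in np.linspace(0, 100, 401)]
    assert all(rank[a] <= rank[b] for a, b in zip(grid, grid[1:]))


def test_status_rejects_out_of_range():
    with pytest.raises(ValueError):
        call_mutational_status(101.0)


def test_cdr3_matches_simulated_truth(db):
    for seed in range(15):
        rr = simulate_rearrangement(db, rng_seed=seed)
        aa, nt, flags = extract_cdr3(_rearr_from_truth(rr), db)
        assert aa == rr.true_cdr3_aa
        assert nt == rr.true_cdr3_nt
        assert aa.startswith("C") and aa.endswith("W")


def test_cdr3_zero_noise_pipeline_recovery(clean_run):
    sample, result = clean_run
    truth = {r.clone_id: r.true_cdr3_aa for r in sample.rearrangements}
    for r in result.rearrangements:
        assert r.annotation.cdr3_aa == truth[r.name]


def test_stop_codon_junction_flagged_unproductive(db):
    rr = simulate_rearrangement(db, shm_rate=0.0, rng_seed=2)
    v_len = len(rr.v_mutated)
    # junction forcing TAA stops across the CDR3 in the anchored frame
    bad = rr.v_mutated + "TAATAATAA" + db[rr.j_name].sequence
    rearr = _rearr_from_truth(rr)
    rearr.consensus = bad
    rearr.junction_insert = "TAATAATAA"
    rearr.junction_interval = (v_len, v_len + 9)
    aa, nt, flags = extract_cdr3(rearr, db)
    assert aa is None and nt is None
    assert "unproductive" in flags


def test_missing_wgxg_motif_yields_absent_cdr3(db):
    rr = simulate_rearrangement(db, shm_rate=0.0, rng_seed=2)
    j = db[rr.j_name].sequence
    w = j.find("TGGGG")
    crippled = j[:w] + "AGG" + j[w + 3:]  # Trp118 codon knocked out
    rearr = _rearr_from_truth(rr)
    rearr.consensus = rr.v_mutated + rr.true_junction + crippled
    aa, nt, _ = extract_cdr3(rearr, db)
    assert aa is None and nt is None


def test_infer_d_recovers_untruncated_insert(db):
    rr = simulate_rearrangement(db, shm_rate=0.0, rng_seed=6)
    d_full = db[rr.d_name].sequence
    rearr = _rearr_from_truth(rr)
    junction = "ACGT" + d_full + "TTAA"
    v_len = len(rr.v_mutated)
    rearr.consensus = rr.v_mutated + junction + db[rr.j_name].sequence
    rearr.junction_insert = junction
    rearr.junction_interval = (v_len, v_len + len(junction))
    assert infer_d(rearr, db) == rr.d_name


def test_infer_d_absent_for_random_or_empty_junction(db):
    rr = simulate_rearrangement(db, shm_rate=0.0, rng_seed=2)
    rearr = _rearr_from_truth(rr)
    rearr.junction_insert = "ACCTGATCGA"  # short random N-nucleotides
    assert infer_d(rearr, db) is None
    rearr.junction_insert = ""
    assert infer_d(rearr, db) is None


def test_extra_substitutions_never_raise_identity(db):
    rr = simulate_rearrangement(db, shm_rate=0.02, rng_seed=9)
    rearr = _rearr_from_truth(rr)
    base_identity, _, _ = v_identity(rearr, db)
    v = list(rearr.consensus)
    rng = np.random.default_rng(0)
    for k in rng.choice(200, size=8, replace=False):
        v[k] = {"A": "C", "C": "G", "G": "T", "T": "A"}[v[k]]
    rearr.consensus = "".join(v)
    worse, _, _ = v_identity(rearr, db)
    assert worse <= base_identity


def test_annotate_sets_full_record(db, clean_run):
    _, result = clean_run
    top = max(result.rearrangements, key=lambda r: r.read_count)
    ann = annotate_rearrangement(top, db)
    assert ann.identity_pct == 100.0
    assert ann.mutational_status == "UM"
    assert ann.cdr3_aa is not None
    assert top.annotation is ann
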