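"""Shared fixtures: synthetic germline database and pipeline runs.

Heavy simulated runs are session-scoped so round-trip, SHM-recovery and
error-correction checks across modules reuse the same alignments.
"""

from __future__ import annotations

import pytest

from ighrep.pipeline import RunConfig, run_sample
from ighrep.simulate import default_amplicons, make_synthetic_germline, simulate_sample


@pytest.fixture(scope="session")
def db():
    return make_synthetic_germline(seed=1)


@pytest.fixture(scope="session")
def clean_run(db):
    """Zero-noise four-clone sample (abundances 45/30/15/10%) and its
    pipeline result: the exact-recovery surface."""
    sample = simulate_sample(
        db,
        n_reads=500,
        shm_rate=0.0,
        error_rate=0.0,
        rng_seed=11,
        abundances=[0.45, 0.30, 0.15, 0.10],
        sample_id="clean",
    )
    result = run_sample(RunConfig(), db, sample.r1, sample.r2, "clean")
    return sample, result


@pytest.fixture(scope="session")
def shm_run(db):
    """Single clone at 5% SHM and 0.5% sequencing error, sequenced with the
    leader-inclusive four-amplicon design so the whole V region is covered
    (SHM-recovery surface)."""
    v_len = len(db.segment("V")[0].sequence)
    amplicons = default_amplicons(v_len, include_leader=True)
    sample = simulate_sample(
        db,
        n_reads=400,
        shm_rate=0.05,
        error_rate=0.005,
        amplicons=amplicons,
        rng_seed=7,
        n_clones=1,
        sample_id="shm",
    )
    config = RunConfig(amplicons=[[a.label, a.offset] for a in amplicons])
    result = run_sample(config, db, sample.r1, sample.r2, "shm")
    return sample, result


@pytest.fixture(scope="session")
def noisy_run(db):
    """Single clone at 1% sequencing error, no SHM: the consensus
    error-correction surface."""
    sample = simulate_sample(
        db,
        n_reads=200,
        shm_rate=0.0,
        error_rate=0.01,
        rng_seed=23,
        n_clones=1,
        sample_id="noisy",
    )
    result = run_sample(RunConfig(), db, sample.r1, sample.r2, "noisy")
    return sample, result
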