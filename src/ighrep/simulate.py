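"""Synthetic repertoire and read simulator.

Everything the pipeline consumes can be generated here with no downloads:
a synthetic germline allele database (random coding sequences under
realistic IMGT-style allele names, carrying the two structural anchors the
biology provides — a 3' cysteine codon in each V allele, Cys104, and a
WGxG-encoding motif in each J allele whose tryptophan is Trp118), ground
truth VDJ rearrangements with junctional N-nucleotides, a truncated D
insert and per-base somatic hypermutation in the V region, repertoire
abundance profiles (polyclonal vs one or two dominant clones), and 2x150 bp
paired amplicon reads anchored at framework-region primer offsets with
i.i.d. substitution errors and Phred qualities.

All randomness flows from one explicit seed; every output is reproducible.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .germline import GermlineAllele, GermlineDB

# J-region core encoding W-G-Q-G ... (Trp118 = first codon) plus a short
# constant tail, mirroring the layout of real IGHJ alleles.
_J_CORE = "TGGGGCCAAGGAACCCTGGTCACCGTCTCCTCAG"

_V_NAMES = [
    "IGHV1-2*04", "IGHV1-69*09", "IGHV1-69*06", "IGHV1-69D*01", "IGHV3-7*04",
    "IGHV3-11*06", "IGHV3-23*01", "IGHV4-34*01", "IGHV4-39*01", "IGHV5-10-1*03",
    "IGHV1-18*01", "IGHV3-48*02", "IGHV2-5*02", "IGHV6-1*01", "IGHV4-59*01",
    "IGHV3-30*03",
]
_D_NAMES = [
    "IGHD1-1*01", "IGHD2-2*01", "IGHD3-10*01", "IGHD3-22*01",
    "IGHD4-17*01", "IGHD5-12*01", "IGHD6-19*01", "IGHD2-15*01",
]
_J_NAMES = ["IGHJ1*01", "IGHJ2*01", "IGHJ3*02", "IGHJ4*02", "IGHJ5*02", "IGHJ6*02"]

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]


def _random_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(_CODONS[i] for i in rng.integers(0, len(_CODONS), size=n))


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def make_synthetic_germline(
    n_v: int = 12,
    n_d: int = 8,
    n_j: int = 6,
    v_len: int = 294,
    seed: int = 0,
) -> GermlineDB:
    """Build a synthetic germline V/D/J database (synthetic stand-in for a
    real IMGT export; names are realistic, sequences are random coding DNA).

    Every V allele has length ``v_len`` (a multiple of 3) and ends with
    TGT-GCG-AGA (Cys-Ala-Arg), placing the Cys104 codon at ``v_len - 9``.
    Every J allele is a random prefix followed by a W-G-Q-G core, so Trp118
    sits at the prefix length.  D alleles are short random inserts.
    """
    if v_len % 3 != 0:
        raise ValueError("v_len must be a multiple of 3")
    rng = np.random.default_rng(seed)
    db = GermlineDB()
    from .germline import parse_allele_name

    for name in _V_NAMES[:n_v]:
        seq = _random_codons(rng, (v_len - 9) // 3) + "TGTGCGAGA"
        t = parse_allele_name(name)
        db.add(GermlineAllele(t.name, t.segment, t.family, t.gene, t.allele_num, seq))
    for name in _D_NAMES[:n_d]:
        seq = _random_nt(rng, int(rng.integers(16, 25)))
        t = parse_allele_name(name)
        db.add(GermlineAllele(t.name, t.segment, t.family, t.gene, t.allele_num, seq))
    for name in _J_NAMES[:n_j]:
        prefix_len = int(rng.integers(9, 16))
        while True:
            prefix = _random_nt(rng, prefix_len)
            if "TGGGG" not in prefix + _J_CORE[:4]:
                break
        t = parse_allele_name(name)
        db.add(
            GermlineAllele(t.name, t.segment, t.family, t.gene, t.allele_num, prefix + _J_CORE)
        )
    return db


@dataclass
class AmpliconSpec:
    """One forward amplicon: nested forward primer at ``offset`` within the
    V allele, shared reverse anchor at the 3' end of the rearrangement."""

    label: str  # "leader", "FR1", "FR2" or "FR3"
    offset: int  # 0-based forward-primer position within the V allele


def default_amplicons(v_len: int = 294, include_leader: bool = False) -> list[AmpliconSpec]:
    """Nested FR amplicons tiling the V region with overlapping 150 bp reads:
    FR1 at ~0.25|V|, FR2 at ~0.5|V|, FR3 at ~0.75|V| (leader at 0 for the
    cDNA-style four-amplicon design)."""
    specs = []
    if include_leader:
        specs.append(AmpliconSpec("leader", 0))
    specs += [
        AmpliconSpec("FR1", round(0.25 * v_len)),
        AmpliconSpec("FR2", round(0.50 * v_len)),
        AmpliconSpec("FR3", round(0.75 * v_len)),
    ]
    return specs


@dataclass
class SimulatedRearrangement:
    """Ground-truth record for one simulated VDJ rearrangement."""

    v_name: str
    d_name: str
    j_name: str
    n1: str
    n2: str
    shm_rate: float
    v_germline: str
    v_mutated: str
    d_fragment: str
    true_sequence: str
    true_junction: str
    true_cdr3_nt: str
    true_cdr3_aa: str
    n_mutations: int
    abundance: float = 1.0

    @property
    def clone_id(self) -> str:
        return f"{self.v_name}_{self.j_name}"


def _apply_shm(
    rng: np.random.Generator, v_seq: str, shm_rate: float, protect_tail: int = 9
) -> tuple[str, int]:
    """Independent per-base substitutions at ``shm_rate`` over the V region,
    sparing the last ``protect_tail`` nt (the Cys104 anchor codon region) so
    the truth CDR3 stays well defined."""
    if shm_rate <= 0:
        return v_seq, 0
    bases = list(v_seq)
    n_mut = 0
    mutable = len(v_seq) - protect_tail
    hits = rng.random(mutable) < shm_rate
    for i in np.flatnonzero(hits):
        alternatives = [b for b in "ACGT" if b != bases[i]]
        bases[i] = alternatives[int(rng.integers(0, 3))]
        n_mut += 1
    return "".join(bases), n_mut


def simulate_rearrangement(
    db: GermlineDB,
    shm_rate: float = 0.0,
    rng_seed: int | np.random.Generator = 0,
    v_name: str | None = None,
    j_name: str | None = None,
    productive: bool = True,
    max_tries: int = 100,
) -> SimulatedRearrangement:
    """Simulate one VDJ rearrangement.

    V/D/J are drawn uniformly (or pinned by name), the D insert is truncated
    by 0-5 nt at each end, N1/N2 junction nucleotides are drawn with lengths
    0-10, and SHM is applied as independent substitutions in the V region.
    With ``productive=True`` the N2 length is padded so Cys104 and Trp118
    share a reading frame, and junctions creating stop codons or a premature
    WGxG inside the CDR3 are resampled.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    for seg in ("V", "D", "J"):
        if not db.segment(seg):
            raise ValueError(f"germline database has no {seg} alleles")

    v = db[v_name] if v_name else db.segment("V")[int(rng.integers(0, len(db.segment("V"))))]
    d = db.segment("D")[int(rng.integers(0, len(db.segment("D"))))]
    j = db[j_name] if j_name else db.segment("J")[int(rng.integers(0, len(db.segment("J"))))]

    v_mut, n_mut = _apply_shm(rng, v.sequence, shm_rate)
    cys_start = len(v_mut) - 9
    w_off = j.sequence.find("TGGGG")
    if w_off < 0:
        raise ValueError(f"J allele {j.name} lacks a WGxG-encoding motif")

    for _ in range(max_tries):
        lt, rt = int(rng.integers(0, 6)), int(rng.integers(0, 6))
        d_frag = d.sequence[lt: len(d.sequence) - rt]
        n1 = _random_nt(rng, int(rng.integers(0, 11)))
        n2 = _random_nt(rng, int(rng.integers(0, 11)))
        if productive:
            pad = (-(w_off + len(n1) + len(d_frag) + len(n2))) % 3
            n2 += _random_nt(rng, pad)
        junction = n1 + d_frag + n2
        seq = v_mut + junction + j.sequence
        cdr3_nt = seq[cys_start: len(v_mut) + len(junction) + w_off + 3]
        if not productive:
            aa = str(Seq(cdr3_nt[: len(cdr3_nt) - len(cdr3_nt) % 3]).translate())
            break
        aa = str(Seq(cdr3_nt).translate())
        tail_nt = seq[cys_start:]
        tail = str(Seq(tail_nt[: len(tail_nt) - len(tail_nt) % 3]).translate())
        m = re.search(r"WG.G", tail)
        if (
            "*" not in aa
            and aa.startswith("C")
            and aa.endswith("W")
            and m is not None
            and m.start() == len(aa) - 1
        ):
            break
    else:
        raise RuntimeError("could not build a productive junction")

    return SimulatedRearrangement(
        v_name=v.name,
        d_name=d.name,
        j_name=j.name,
        n1=n1,
        n2=n2,
        shm_rate=shm_rate,
        v_germline=v.sequence,
        v_mutated=v_mut,
        d_fragment=d_frag,
        true_sequence=seq,
        true_junction=junction,
        true_cdr3_nt=cdr3_nt,
        true_cdr3_aa=aa if productive else "",
        n_mutations=n_mut,
    )


def simulate_profile(
    kind: str,
    n_background: int = 30,
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw a clone-abundance profile (descending fractions summing to 1).

    ``polyclonal``: near-flat profile whose maximum consecutive ratio is
    planted in [1.5, 3.7] (healthy-donor-like; no dominant clone).
    ``one_clone``: a dominant clone whose ratio to the next clone is
    log-uniform on [8.3, 900].
    ``two_clone``: two dominant clones with mutual ratio < 8 (uniform on
    [1.05, 3.5]) and a second/third ratio log-uniform on [8.3, 400].
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if n_background < 10:
        raise ValueError("n_background must be >= 10")

    def _background(n: int, first: float) -> list[float]:
        out, cur = [], first
        for _ in range(n):
            out.append(cur)
            cur /= rng.uniform(1.02, 1.35)
        return out

    # The top background clone must survive the downstream <0.1% abundance
    # filter, or the dominant/next gap would be measured against nothing;
    # 0.25% of the (approximate) total keeps it clear of the filter.
    def _bg_floor(dominant_sum: float) -> float:
        return 0.0025 * (1.0 + dominant_sum)

    if kind == "polyclonal":
        ratios = rng.uniform(1.02, 1.35, size=n_background - 1)
        # plant the maximum consecutive ratio in the healthy-donor range, in
        # the upper half of the profile so the <0.1% tail filter keeps it
        ratios[int(rng.integers(0, max(1, (n_background - 1) // 2)))] = rng.uniform(1.5, 3.7)
        pcts, cur = [1.0], 1.0
        for r in ratios:
            cur /= r
            pcts.append(cur)
    elif kind == "one_clone":
        r = 10 ** rng.uniform(np.log10(8.3), np.log10(900.0))
        pcts = [1.0] + _background(n_background, max(1.0 / r, _bg_floor(0.0)))
    elif kind == "two_clone":
        r12 = rng.uniform(1.05, 3.5)
        r23 = 10 ** rng.uniform(np.log10(8.3), np.log10(400.0))
        c2 = 1.0 / r12
        pcts = [1.0, c2] + _background(n_background, max(c2 / r23, _bg_floor(c2)))
    else:
        raise ValueError(f"unknown profile kind {kind!r}")

    arr = np.asarray(pcts, dtype=float)
    arr = np.sort(arr)[::-1]
    return arr / arr.sum()


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _make_record(read_id: str, seq: str, qual: list[int]) -> SeqRecord:
    rec = SeqRecord(Seq(seq), id=read_id, description="")
    rec.letter_annotations["phred_quality"] = qual
    return rec


def generate_reads(
    rearr: SimulatedRearrangement,
    amplicons: list[AmpliconSpec],
    n_reads: int,
    error_rate: float = 0.0,
    rng_seed: int | np.random.Generator = 0,
    read_len: int = 150,
    base_quality: int = 37,
    lowq_tail: int = 0,
    id_prefix: str = "read",
    proportions: list[float] | None = None,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Generate ``n_reads`` 150 bp read pairs from the rearrangement.

    Pairs are split across amplicons (equal thirds by default); each
    fragment runs from the amplicon's forward offset to the 3' end of the
    rearrangement, R1 reads its 5' end and R2 the reverse complement of its
    3' end.  Substitution errors are i.i.d. at ``error_rate``; qualities are
    constant at ``base_quality`` except for an optional low-quality tail
    (Phred 2 over the last ``lowq_tail`` bases) to exercise trimming.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    seq = rearr.true_sequence
    v_len = len(rearr.v_mutated)
    for amp in amplicons:
        if amp.offset >= len(seq) or amp.offset >= v_len:
            raise ValueError(
                f"amplicon {amp.label} (offset {amp.offset}) does not fit in rearrangement"
            )
    k = len(amplicons)
    if proportions is None:
        counts = [n_reads // k] * k
        for i in range(n_reads - sum(counts)):
            counts[i] += 1
    else:
        counts = [int(round(n_reads * p)) for p in proportions]
        counts[0] += n_reads - sum(counts)

    def _with_errors(s: str) -> str:
        if error_rate <= 0:
            return s
        b = list(s)
        for i in np.flatnonzero(rng.random(len(b)) < error_rate):
            b[i] = [x for x in "ACGT" if x != b[i]][int(rng.integers(0, 3))]
        return "".join(b)

    def _qual(n: int) -> list[int]:
        q = [base_quality] * n
        if lowq_tail > 0:
            for i in range(max(0, n - lowq_tail), n):
                q[i] = 2
        return q

    r1_out: list[SeqRecord] = []
    r2_out: list[SeqRecord] = []
    for amp, n_amp in zip(amplicons, counts):
        frag = seq[amp.offset:]
        fwd = frag[:read_len]
        rev = _revcomp(frag[-read_len:] if len(frag) >= read_len else frag)
        for i in range(n_amp):
            rid = f"{id_prefix}:{amp.label}:{i}"
            r1_out.append(_make_record(rid, _with_errors(fwd), _qual(len(fwd))))
            r2_out.append(_make_record(rid, _with_errors(rev), _qual(len(rev))))
    return r1_out, r2_out


@dataclass
class SimulatedSample:
    """One simulated sample: clones with abundances plus the paired reads."""

    sample_id: str
    kind: str
    rearrangements: list[SimulatedRearrangement]
    r1: list[SeqRecord]
    r2: list[SeqRecord]

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample": self.sample_id,
                "clone_id": r.clone_id,
                "v": r.v_name,
                "d": r.d_name,
                "j": r.j_name,
                "cdr3_aa": r.true_cdr3_aa,
                "abundance": r.abundance,
                "shm_rate": r.shm_rate,
            }
            for r in self.rearrangements
        ]
        return pd.DataFrame(
            rows,
            columns=["sample", "clone_id", "v", "d", "j", "cdr3_aa", "abundance", "shm_rate"],
        )


def simulate_sample(
    db: GermlineDB,
    kind: str = "one_clone",
    n_reads: int = 600,
    shm_rate: float = 0.0,
    error_rate: float = 0.0,
    amplicons: list[AmpliconSpec] | None = None,
    rng_seed: int | np.random.Generator = 0,
    n_clones: int | None = None,
    n_background: int = 10,
    sample_id: str = "sample1",
    abundances: list[float] | None = None,
) -> SimulatedSample:
    """Simulate a full sample: an abundance profile, one ground-truth
    rearrangement per clone (each clone on a distinct V-J combination, the
    key the pipeline reconstructs), and paired amplicon reads allocated to
    clones in proportion to abundance.

    ``n_clones`` caps how many of the most abundant profile clones receive
    reads (low-abundance background tails are pointless at small depth);
    ``abundances`` bypasses the profile draw with explicit clone fractions.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if amplicons is None:
        v_len = len(db.segment("V")[0].sequence)
        amplicons = default_amplicons(v_len)
    if abundances is not None:
        profile = np.asarray(abundances, dtype=float)
        profile = np.sort(profile)[::-1] / profile.sum()
    else:
        profile = simulate_profile(kind, n_background=n_background, rng_seed=rng)
    if n_clones is not None:
        profile = profile[:n_clones] / profile[:n_clones].sum()

    combos = list(
        itertools.product(
            [a.name for a in db.segment("V")], [a.name for a in db.segment("J")]
        )
    )
    if len(combos) < len(profile):
        raise ValueError("not enough distinct V-J combinations for the profile")
    picks = rng.choice(len(combos), size=len(profile), replace=False)

    # largest-remainder allocation of read pairs to clones
    raw = profile * n_reads
    alloc = np.floor(raw).astype(int)
    remainder = n_reads - alloc.sum()
    order = np.argsort(-(raw - alloc))
    for i in order[:remainder]:
        alloc[i] += 1

    rearrs: list[SimulatedRearrangement] = []
    r1_all: list[SeqRecord] = []
    r2_all: list[SeqRecord] = []
    for ci, (abund, n_pairs) in enumerate(zip(profile, alloc)):
        v_name, j_name = combos[picks[ci]]
        rr = simulate_rearrangement(
            db, shm_rate=shm_rate, rng_seed=rng, v_name=v_name, j_name=j_name
        )
        rr.abundance = float(abund)
        rearrs.append(rr)
        if n_pairs > 0:
            r1, r2 = generate_reads(
                rr,
                amplicons,
                int(n_pairs),
                error_rate=error_rate,
                rng_seed=rng,
                id_prefix=f"{sample_id}:c{ci}",
            )
            r1_all.extend(r1)
            r2_all.extend(r2)
    return SimulatedSample(sample_id, kind, rearrs, r1_all, r2_all)


def write_fastq(records: list[SeqRecord], path: str | Path) -> None:
    SeqIO.write(records, str(path), "fastq")


def write_truth_csv(samples: list[SimulatedSample], path: str | Path) -> None:
    frame = pd.concat([s.truth_frame() for s in samples], ignore_index=True)
    frame.to_csv(path, index=False)
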