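"""Consensus annotation: germline V identity, SHM status, CDR3 and IGHD.

The percent identity of the consensus V portion to its assigned germline V
allele quantifies somatic hypermutation.  Identity is computed by pairwise
local alignment over the V region only — the junction and J are excluded,
matching how V-region identity is conventionally reported (IMGT/V-QUEST
style).  Mutational status follows the ERIC convention for CLL: UM
(unmutated) at >= 98% identity, MM (mutated) below 97%, and a borderline
band for [97, 98).

The CDR3 is delimited by the two conserved junction anchors: the second
cysteine of the V region (Cys104) and the J-region tryptophan (Trp118),
the W of the W-G-x-G motif.  Cys104 is located through the germline V
alignment (with a last-Cys-in-the-final-36-nt fallback), the reading frame
follows from its position, and the translated consensus is scanned
downstream for the WGxG motif.  A junction with no motif-satisfying frame
or an in-frame stop codon is reported as unproductive, not an error.

IGHD is not part of the concatenated V-J reference, so it is inferred from
the junction insert: the best locally aligned D allele is reported when the
alignment carries a contiguous match run of at least 8 nt at >= 80%
identity (N-nucleotides are expected to flank the D core).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .assign import make_aligner
from .consensus import Rearrangement
from .germline import GermlineDB

DEFAULT_UM_THRESHOLD = 98.0
DEFAULT_BORDERLINE_FLOOR = 97.0
DEFAULT_D_MIN_RUN = 8
DEFAULT_D_MIN_IDENTITY = 80.0
_ARTIFACT_IDENTITY_FLOOR = 60.0
_CYS_WINDOW = 36  # nt window at the V 3' end searched for the Cys104 codon


@dataclass
class Annotation:
    identity_pct: float | None = None
    mutational_status: str | None = None  # "UM", "borderline" or "MM"
    status_note: str = ""
    cdr3_aa: str | None = None
    cdr3_nt: str | None = None
    d_allele: str | None = None
    mutations: list[tuple[int, str, str]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def v_identity(
    rearr: Rearrangement, db: GermlineDB, aligner=None
) -> tuple[float, list[tuple[int, str, str]], list[str]]:
    """Percent identity of the consensus V portion vs its germline V allele.

    Returns (identity, substitution list with 0-based V-allele coordinates,
    flags).  Identity = 100 x matches / aligned columns, junction excluded.
    Identity below 60% flags the rearrangement as an artifact candidate.
    """
    if aligner is None:
        aligner = make_aligner()
    v_part = rearr.consensus[: rearr.junction_interval[0]]
    germ = db[rearr.v_allele].sequence
    if len(v_part) < 100:
        raise ValueError(
            f"consensus V portion too short ({len(v_part)} nt) for {rearr.name}"
        )
    aln = aligner.align(germ, v_part)[0]
    counts = aln.counts()
    aligned_cols = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / aligned_cols if aligned_cols else 0.0
    mutations = []
    for (r0, r1), (q0, q1) in zip(*aln.aligned):
        for k in range(r1 - r0):
            if germ[r0 + k] != v_part[q0 + k]:
                mutations.append((r0 + k, germ[r0 + k], v_part[q0 + k]))
    flags = ["artifact_candidate"] if identity < _ARTIFACT_IDENTITY_FLOOR else []
    return identity, mutations, flags


def call_mutational_status(
    identity_pct: float,
    um_threshold: float = DEFAULT_UM_THRESHOLD,
    borderline_floor: float = DEFAULT_BORDERLINE_FLOOR,
) -> str:
    """UM at >= 98% identity, borderline in [97, 98), MM below 97.

    A pure function of the identity; the 98.0 boundary itself is UM.
    """
    if not 0.0 <= identity_pct <= 100.0:
        raise ValueError(f"identity out of range: {identity_pct}")
    if identity_pct >= um_threshold:
        return "UM"
    if identity_pct >= borderline_floor:
        return "borderline"
    return "MM"


def _germline_cys_position(germ: str) -> int | None:
    """Last in-frame Cys codon (TGT/TGC) within the final window of the
    germline V allele, assuming the allele starts in frame."""
    best = None
    start = max(0, len(germ) - _CYS_WINDOW)
    for pos in range(0, len(germ) - 2, 3):
        if pos >= start and germ[pos: pos + 3] in ("TGT", "TGC"):
            best = pos
    return best


def _map_to_consensus(aln_blocks, ref_pos: int) -> int | None:
    """Map a germline coordinate through gapless alignment blocks."""
    for (r0, r1), (q0, q1) in aln_blocks:
        if r0 <= ref_pos < r1:
            return q0 + (ref_pos - r0)
    return None


def extract_cdr3(
    rearr: Rearrangement, db: GermlineDB, aligner=None
) -> tuple[str | None, str | None, list[str]]:
    """Extract the CDR3 (Cys104..Trp118 inclusive) from the consensus.

    Returns (cdr3_aa, cdr3_nt, flags); (None, None, flags) when no frame
    satisfies both anchors, with an "unproductive" flag when a stop codon
    breaks the junction in the anchored frame.
    """
    if aligner is None:
        aligner = make_aligner()
    v_end = rearr.junction_interval[0]
    v_part = rearr.consensus[:v_end]
    germ = db[rearr.v_allele].sequence

    # primary anchor: germline Cys104 mapped through the V alignment;
    # fallback: Cys codons in the final window of the consensus V, lastmost
    # first
    mapped: int | None = None
    g_cys = _germline_cys_position(germ)
    if g_cys is not None:
        aln = aligner.align(germ, v_part)[0]
        blocks = tuple(
            ((int(r0), int(r1)), (int(q0), int(q1)))
            for (r0, r1), (q0, q1) in zip(*aln.aligned)
        )
        mapped = _map_to_consensus(blocks, g_cys)
    fallback = [
        pos
        for pos in range(v_end - 3, max(-1, v_end - _CYS_WINDOW - 1), -1)
        if v_part[pos: pos + 3] in ("TGT", "TGC") and pos != mapped
    ]
    candidates = ([mapped] if mapped is not None else []) + fallback

    flags: list[str] = []
    for cys in candidates:
        tail = rearr.consensus[cys:]
        tail = tail[: len(tail) - len(tail) % 3]
        aa = str(Seq(tail).translate())
        if not aa.startswith("C"):
            continue
        m = re.search(r"WG.G", aa)
        if m is None:
            stop = aa.find("*")
            if stop != -1:
                flags.append("unproductive")
            continue
        w_idx = m.start()
        cdr3_aa = aa[: w_idx + 1]
        if "*" in cdr3_aa:
            flags.append("unproductive")
            continue
        cdr3_nt = rearr.consensus[cys: cys + 3 * (w_idx + 1)]
        return cdr3_aa, cdr3_nt, flags
    return None, None, sorted(set(flags))


def _longest_match_run(aln, ref: str, query: str) -> int:
    run = best = 0
    for (r0, r1), (q0, q1) in zip(*aln.aligned):
        for k in range(r1 - r0):
            if ref[r0 + k] == query[q0 + k]:
                run += 1
                best = max(best, run)
            else:
                run = 0
        run = 0  # block boundary = gap
    return best


def infer_d(
    rearr: Rearrangement,
    db: GermlineDB,
    min_run: int = DEFAULT_D_MIN_RUN,
    min_identity: float = DEFAULT_D_MIN_IDENTITY,
    aligner=None,
) -> str | None:
    """Best D allele hidden in the junction insert, or None.

    The junction insert is aligned locally against every D allele; the best
    scoring hit is reported when its longest contiguous match run reaches
    ``min_run`` nt at >= ``min_identity``% identity over aligned columns.
    """
    junction = rearr.junction_insert
    if len(junction) < min_run:
        return None
    if aligner is None:
        aligner = make_aligner()
    best_name, best_key = None, None
    for d in db.segment("D"):
        aln = aligner.align(d.sequence, junction)[0]
        counts = aln.counts()
        cols = counts.identities + counts.mismatches + counts.gaps
        if cols == 0:
            continue
        identity = 100.0 * counts.identities / cols
        run = _longest_match_run(aln, d.sequence, junction)
        if run < min_run or identity < min_identity:
            continue
        key = (aln.score, identity, d.name)
        if best_key is None or (key[0], key[1]) > (best_key[0], best_key[1]) or (
            (key[0], key[1]) == (best_key[0], best_key[1]) and d.name < best_name
        ):
            best_name, best_key = d.name, key
    return best_name


def annotate_rearrangement(
    rearr: Rearrangement,
    db: GermlineDB,
    um_threshold: float = DEFAULT_UM_THRESHOLD,
    borderline_floor: float = DEFAULT_BORDERLINE_FLOOR,
    aligner=None,
) -> Annotation:
    """Full annotation of one rearrangement (sets ``rearr.annotation``)."""
    if aligner is None:
        aligner = make_aligner()
    identity, mutations, flags = v_identity(rearr, db, aligner)
    status = call_mutational_status(identity, um_threshold, borderline_floor)
    note = (
        "borderline identity band [97, 98): reported as MM with note"
        if status == "borderline"
        else ""
    )
    cdr3_aa, cdr3_nt, cdr3_flags = extract_cdr3(rearr, db, aligner)
    ann = Annotation(
        identity_pct=identity,
        mutational_status=status,
        status_note=note,
        cdr3_aa=cdr3_aa,
        cdr3_nt=cdr3_nt,
        d_allele=infer_d(rearr, db, aligner=aligner),
        mutations=mutations,
        flags=sorted(set(flags + cdr3_flags)),
    )
    rearr.annotation = ann
    return ann
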