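"""V-J pairing inference and per-rearrangement consensus calling.

Reads carrying both a V and a J hit (on one read, or split across the two
mates of a pair) are the linkage evidence for a V-J allele combination.
Each supported combination's reads are isolated and re-expressed in the
coordinates of the concatenated V-[N gap]-J germline reference; a majority
base is called per reference column, while the junction (the gap in the
reference) is assembled from reads that span it, the most frequent full
junction string winning.  The result is one consensus sequence per
rearrangement with depth and fragment-support metrics — the consensus step
is what corrects sequencing and PCR errors.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assign import ReadAssignment
from .germline import DEFAULT_GAP_LEN, GermlineDB, concat_vj_reference

log = logging.getLogger(__name__)

DEFAULT_MIN_LINK_READS = 3
DEFAULT_MIN_DEPTH = 2

#: slack (nt) allowed between a local alignment's end and the segment
#: boundary when deciding that a read truly spans the V-J junction
_JUNCTION_SLACK = 2

FRAGMENT_LABELS = ("leader", "FR1", "FR2", "FR3", "unknown")


@dataclass
class Pairing:
    """One inferred V-J allele combination with its supporting read units."""

    v_allele: str
    j_allele: str
    linking_ids: list[str]
    member_ids: list[str] = field(default_factory=list)

    @property
    def name(self) -> str:
        return f"{self.v_allele}_{self.j_allele}"


@dataclass
class Rearrangement:
    """One reconstructed IG rearrangement."""

    v_allele: str
    j_allele: str
    consensus: str
    junction_insert: str
    junction_interval: tuple[int, int]  # half-open, consensus coordinates
    read_count: int
    fragment_support: dict[str, int]
    depth_profile: np.ndarray
    clonal_pct: float | None = None
    annotation: object | None = None
    merged_alleles: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def name(self) -> str:
        return f"{self.v_allele}_{self.j_allele}"

    @property
    def v_gene(self) -> str:
        return self.v_allele.split("*")[0]

    @property
    def j_gene(self) -> str:
        return self.j_allele.split("*")[0]

    @property
    def v_family(self) -> str:
        return self.v_gene.split("-", 1)[0]


def _units(assignments: list[ReadAssignment]) -> dict[str, list[ReadAssignment]]:
    """Group assignments into read units (mates of a pair share an id)."""
    units: dict[str, list[ReadAssignment]] = defaultdict(list)
    for a in assignments:
        if a.assigned:
            units[a.read_id].append(a)
    return units


def _unit_alleles(members: list[ReadAssignment]) -> tuple[str | None, str | None]:
    """The unit's V and J allele (best-scoring hit across its mates)."""
    v_best = max(
        (m.v_hit for m in members if m.v_hit), default=None, key=lambda h: h.score
    )
    j_best = max(
        (m.j_hit for m in members if m.j_hit), default=None, key=lambda h: h.score
    )
    return (v_best.allele if v_best else None, j_best.allele if j_best else None)


def infer_pairings(
    assignments: list[ReadAssignment],
    min_link_reads: int = DEFAULT_MIN_LINK_READS,
    pair_level: bool = True,
) -> list[Pairing]:
    """Infer V-J allele combinations from linkage evidence.

    A pairing is created when at least ``min_link_reads`` read units carry
    both the V and the J hit (``pair_level=False`` restricts evidence to
    single reads with both hits).  Units with only a V (or only a J) hit
    are then attached to the pairing of their allele when that pairing is
    unambiguous (most linking reads; ties drop the unit).
    """
    units = _units(assignments)
    link_ids: dict[tuple[str, str], list[str]] = defaultdict(list)
    for uid, members in units.items():
        if pair_level:
            v_allele, j_allele = _unit_alleles(members)
        else:
            both = [m for m in members if m.v_hit and m.j_hit]
            v_allele, j_allele = _unit_alleles(both) if both else (None, None)
        if v_allele and j_allele:
            link_ids[(v_allele, j_allele)].append(uid)

    pairings = [
        Pairing(v, j, sorted(ids), member_ids=sorted(ids))
        for (v, j), ids in sorted(link_ids.items())
        if len(ids) >= min_link_reads
    ]

    by_v: dict[str, list[Pairing]] = defaultdict(list)
    by_j: dict[str, list[Pairing]] = defaultdict(list)
    for p in pairings:
        by_v[p.v_allele].append(p)
        by_j[p.j_allele].append(p)

    claimed = {uid for p in pairings for uid in p.member_ids}
    for uid, members in sorted(units.items()):
        if uid in claimed:
            continue
        v_allele, j_allele = _unit_alleles(members)
        candidates = by_v.get(v_allele, []) if v_allele else by_j.get(j_allele, [])
        if not candidates:
            continue
        best = sorted(candidates, key=lambda p: (-len(p.linking_ids), p.name))
        if len(best) > 1 and len(best[0].linking_ids) == len(best[1].linking_ids):
            continue  # ambiguous between equally supported pairings: drop
        best[0].member_ids.append(uid)
    return pairings


def _vote_column(counts: Counter, ref_base: str, min_depth: int) -> str:
    """Majority base; below min depth or on a tie involving the reference
    the reference base is retained; other ties resolve alphabetically."""
    total = sum(counts.values())
    if total < min_depth:
        return ref_base
    top = max(counts.values())
    winners = sorted(b for b, c in counts.items() if c == top)
    if ref_base in winners:
        return ref_base
    return winners[0]


def build_consensus(
    pairing: Pairing,
    assignments: list[ReadAssignment],
    db: GermlineDB,
    gap_len: int = DEFAULT_GAP_LEN,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> Rearrangement | None:
    """Call the consensus sequence for one V-J pairing.

    Per-column majority vote over the V and J portions of the concatenated
    reference (columns under ``min_depth`` keep the reference base); the
    junction is the most frequent full junction string among reads that
    span both segment boundaries (ties: higher count, then longer, then
    lexicographic).  Returns None (with a log entry) if no member read
    aligns.
    """
    v_ref = db[pairing.v_allele]
    j_ref = db[pairing.j_allele]
    # concatenated reference fixes the coordinate frame we report in
    _, gap = concat_vj_reference(v_ref, j_ref, gap_len)
    v_len, j_len = len(v_ref.sequence), len(j_ref.sequence)

    members = set(pairing.member_ids)
    unit_map = _units(assignments)

    v_counts = [Counter() for _ in range(v_len)]
    j_counts = [Counter() for _ in range(j_len)]
    junctions: Counter = Counter()
    fragment_support: Counter = Counter()
    used_units = 0

    for uid in sorted(members):
        unit = unit_map.get(uid, [])
        aligned_any = False
        frag = "unknown"
        for m in unit:
            if m.fragment != "unknown":
                frag = m.fragment
            if m.v_hit and m.v_hit.allele == pairing.v_allele:
                aligned_any = True
                for (r0, r1), (q0, q1) in m.v_hit.blocks:
                    for k in range(r1 - r0):
                        v_counts[r0 + k][m.seq[q0 + k]] += 1
            if m.j_hit and m.j_hit.allele == pairing.j_allele:
                aligned_any = True
                for (r0, r1), (q0, q1) in m.j_hit.blocks:
                    for k in range(r1 - r0):
                        j_counts[r0 + k][m.seq[q0 + k]] += 1
            # junction candidate: one read whose V alignment reaches the V
            # 3' end and whose J alignment starts at the J 5' end
            if (
                m.v_hit
                and m.j_hit
                and m.v_hit.allele == pairing.v_allele
                and m.j_hit.allele == pairing.j_allele
                and m.v_hit.ref_end >= v_len - _JUNCTION_SLACK
                and m.j_hit.ref_start <= _JUNCTION_SLACK
            ):
                jct_start = m.v_hit.read_end + (v_len - m.v_hit.ref_end)
                jct_end = m.j_hit.read_start - m.j_hit.ref_start
                if jct_start <= jct_end:
                    junctions[m.seq[jct_start:jct_end]] += 1
        if aligned_any:
            used_units += 1
            fragment_support[frag] += 1

    if used_units == 0:
        log.info("pairing %s discarded: no aligned reads", pairing.name)
        return None

    junction = ""
    if junctions:
        junction = sorted(
            junctions.items(), key=lambda kv: (-kv[1], -len(kv[0]), kv[0])
        )[0][0]

    v_call = "".join(
        _vote_column(v_counts[i], v_ref.sequence[i], min_depth) for i in range(v_len)
    )
    j_call = "".join(
        _vote_column(j_counts[i], j_ref.sequence[i], min_depth) for i in range(j_len)
    )
    consensus = v_call + junction + j_call

    depth = np.concatenate(
        [
            np.array([sum(c.values()) for c in v_counts], dtype=int),
            np.full(len(junction), sum(junctions.values()), dtype=int),
            np.array([sum(c.values()) for c in j_counts], dtype=int),
        ]
    )
    return Rearrangement(
        v_allele=pairing.v_allele,
        j_allele=pairing.j_allele,
        consensus=consensus,
        junction_insert=junction,
        junction_interval=(v_len, v_len + len(junction)),
        read_count=used_units,
        fragment_support=dict(fragment_support),
        depth_profile=depth,
    )


def build_rearrangements(
    assignments: list[ReadAssignment],
    db: GermlineDB,
    min_link_reads: int = DEFAULT_MIN_LINK_READS,
    gap_len: int = DEFAULT_GAP_LEN,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[Rearrangement]:
    """Pairing inference + consensus for a whole sample."""
    pairings = infer_pairings(assignments, min_link_reads=min_link_reads)
    out = []
    for p in pairings:
        r = build_consensus(p, assignments, db, gap_len=gap_len, min_depth=min_depth)
        if r is not None:
            out.append(r)
    return clonal_percentages(out)


def coverage_breadth(rearr: Rearrangement, depth_floor: int = 500) -> float:
    """Percent of consensus positions with depth >= ``depth_floor``."""
    depth = np.asarray(rearr.depth_profile)
    if depth.size == 0:
        raise ValueError("empty depth profile")
    return 100.0 * float(np.count_nonzero(depth >= depth_floor)) / depth.size


def clonal_percentages(rearrs: list[Rearrangement]) -> list[Rearrangement]:
    """Set each rearrangement's percentage of total IGH-assigned reads."""
    total = sum(r.read_count for r in rearrs)
    for r in rearrs:
        r.clonal_pct = 100.0 * r.read_count / total if total else None
    return rearrs


def rearrangement_frame(rearrs: list[Rearrangement], depth_floor: int = 500) -> pd.DataFrame:
    rows = []
    for r in rearrs:
        row = {
            "rearrangement": r.name,
            "v_allele": r.v_allele,
            "j_allele": r.j_allele,
            "read_count": r.read_count,
            "clonal_pct": round(r.clonal_pct, 4) if r.clonal_pct is not None else "",
            "coverage_breadth": round(coverage_breadth(r, depth_floor), 2),
            "junction_len": len(r.junction_insert),
        }
        for label in FRAGMENT_LABELS:
            row[f"{label}_reads"] = r.fragment_support.get(label, 0)
        rows.append(row)
    cols = [
        "rearrangement", "v_allele", "j_allele", "read_count", "clonal_pct",
        "coverage_breadth", "junction_len",
    ] + [f"{label}_reads" for label in FRAGMENT_LABELS]
    return pd.DataFrame(rows, columns=cols)
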