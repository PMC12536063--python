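"""Mapping-artifact collapse and sample-level QC.

Nonspecific V-gene mapping splits one biological rearrangement over
several sibling alleles or genes; the filter merges these back into the
predominant rearrangement in two stages: (1) consensus identity >= 95%,
first between alleles of the same V gene and then across V genes; (2)
low-support rearrangements (a single fragment class, or an FR3 read share
of at least 92%) are absorbed into the largest rearrangement sharing their
V family and CDR3 amino-acid sequence.  Read counts and fragment support
are summed into the absorber, whose consensus and annotation are retained;
every merge is recorded as an auditable event.  The final report is
summarized at the V gene level while keeping allele detail.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .consensus import FRAGMENT_LABELS, Rearrangement, clonal_percentages

DEFAULT_MERGE_IDENTITY = 95.0
DEFAULT_FR3_FRAC = 0.92
DEFAULT_READ_FLOOR = 1000


@dataclass
class MergeEvent:
    absorbed_id: str
    absorber_id: str
    rule: str  # allele_identity95 | gene_identity95 | single_fragment | fr3_dominant
    identity_at_merge: float | None = None


def make_overlap_aligner():
    """Global aligner with free terminal gaps: identity is judged over the
    mutual overlap of two consensuses that can differ in length, but the
    whole molecules must agree — a shared V segment alone must not look
    identical the way a local alignment would make it."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


def consensus_identity(a: str, b: str, aligner=None) -> float:
    """Percent identity between two consensuses over their mutual overlap
    (end-gap-free global alignment; terminal overhangs are excluded,
    internal differences all count)."""
    if aligner is None:
        aligner = make_overlap_aligner()
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    cols = counts.identities + counts.mismatches + counts.internal_gaps
    return 100.0 * counts.identities / cols if cols else 0.0


def _absorb(absorber: Rearrangement, absorbed: Rearrangement) -> None:
    absorber.read_count += absorbed.read_count
    for k, v in absorbed.fragment_support.items():
        absorber.fragment_support[k] = absorber.fragment_support.get(k, 0) + v
    absorber.merged_alleles.append(absorbed.v_allele)
    absorber.merged_alleles.extend(absorbed.merged_alleles)


def merge_by_identity(
    rearrs: list[Rearrangement],
    threshold: float = DEFAULT_MERGE_IDENTITY,
    aligner=None,
) -> tuple[list[Rearrangement], list[MergeEvent]]:
    """Two-pass identity merge: same V gene first, then across V genes.

    Candidates must share the J allele: the artifact mechanism is
    nonspecific V mapping of one rearrangement, not V-J recombination.
    They are visited in descending read count (largest absorbs), so the
    outcome is deterministic and order-independent for a fixed abundance
    ranking.
    """
    if aligner is None:
        aligner = make_overlap_aligner()
    events: list[MergeEvent] = []
    alive = sorted(rearrs, key=lambda r: (-r.read_count, r.name))

    for rule, same_gene in (("allele_identity95", True), ("gene_identity95", False)):
        merged = True
        while merged:
            merged = False
            alive.sort(key=lambda r: (-r.read_count, r.name))
            for i, big in enumerate(alive):
                for small in alive[i + 1:]:
                    if big.j_allele != small.j_allele:
                        continue
                    if same_gene and big.v_gene != small.v_gene:
                        continue
                    if not same_gene and big.v_gene == small.v_gene:
                        continue
                    ident = consensus_identity(big.consensus, small.consensus, aligner)
                    if ident >= threshold:
                        _absorb(big, small)
                        events.append(MergeEvent(small.name, big.name, rule, ident))
                        alive.remove(small)
                        merged = True
                        break
                if merged:
                    break
    return clonal_percentages(alive), events


def merge_low_support(
    rearrs: list[Rearrangement],
    fr3_frac: float = DEFAULT_FR3_FRAC,
) -> tuple[list[Rearrangement], list[MergeEvent]]:
    """Absorb single-fragment or FR3-dominated rearrangements.

    A rearrangement supported by exactly one fragment class, or whose FR3
    reads make up at least ``fr3_frac`` of its reads, joins the largest
    rearrangement with the same V family and the same CDR3 amino-acid
    sequence.  Without such a major it is kept but flagged "low-support".
    """
    events: list[MergeEvent] = []
    alive = sorted(rearrs, key=lambda r: (-r.read_count, r.name))
    for r in list(alive):
        if r not in alive:
            continue
        support = {k: v for k, v in r.fragment_support.items() if v > 0}
        fr3_share = r.fragment_support.get("FR3", 0) / r.read_count if r.read_count else 0.0
        single = len(support) == 1
        fr3_dom = fr3_share >= fr3_frac
        if not (single or fr3_dom):
            continue
        cdr3 = r.annotation.cdr3_aa if r.annotation else None
        majors = [
            m
            for m in alive
            if m is not r
            and m.read_count > r.read_count
            and m.v_family == r.v_family
            and m.annotation is not None
            and cdr3 is not None
            and m.annotation.cdr3_aa == cdr3
        ]
        if not majors:
            if "low-support" not in r.flags:
                r.flags.append("low-support")
            continue
        major = sorted(majors, key=lambda m: (-m.read_count, m.name))[0]
        rule = "fr3_dominant" if fr3_dom else "single_fragment"
        _absorb(major, r)
        events.append(MergeEvent(r.name, major.name, rule, None))
        alive.remove(r)
    return clonal_percentages(alive), events


def apply_artifact_filter(
    rearrs: list[Rearrangement],
    threshold: float = DEFAULT_MERGE_IDENTITY,
    fr3_frac: float = DEFAULT_FR3_FRAC,
) -> tuple[list[Rearrangement], list[MergeEvent]]:
    out, ev1 = merge_by_identity(rearrs, threshold)
    out, ev2 = merge_low_support(out, fr3_frac)
    return out, ev1 + ev2


def summarize_gene_level(rearrs: list[Rearrangement]) -> pd.DataFrame:
    """Gene-level report keyed by (V gene, J gene, CDR3) with allele detail
    nested; clonal percentages recomputed after merging."""
    clonal_percentages(rearrs)
    groups: dict[tuple, list[Rearrangement]] = {}
    for r in rearrs:
        cdr3 = r.annotation.cdr3_aa if r.annotation and r.annotation.cdr3_aa else ""
        groups.setdefault((r.v_gene, r.j_gene, cdr3), []).append(r)
    rows = []
    for (v_gene, j_gene, cdr3), members in sorted(
        groups.items(), key=lambda kv: -sum(m.read_count for m in kv[1])
    ):
        read_count = sum(m.read_count for m in members)
        alleles = sorted(
            {m.v_allele for m in members}
            | {a for m in members for a in m.merged_alleles}
        )
        lead = sorted(members, key=lambda m: (-m.read_count, m.name))[0]
        ann = lead.annotation
        row = {
            "v_gene": v_gene,
            "j_gene": j_gene,
            "cdr3_aa": cdr3,
            "v_alleles": ";".join(alleles),
            "hts": lead.name,
            "read_count": read_count,
            "clonal_pct": round(sum(m.clonal_pct or 0 for m in members), 4),
            "identity_pct": round(ann.identity_pct, 2) if ann and ann.identity_pct is not None else "",
            "status": ann.mutational_status if ann else "",
            "d_allele": ann.d_allele or "" if ann else "",
            "flags": ";".join(sorted({f for m in members for f in m.flags})),
        }
        for label in FRAGMENT_LABELS:
            row[f"{label}_reads"] = sum(m.fragment_support.get(label, 0) for m in members)
        rows.append(row)
    cols = [
        "v_gene", "j_gene", "cdr3_aa", "v_alleles", "hts", "read_count",
        "clonal_pct", "identity_pct", "status", "d_allele", "flags",
    ] + [f"{label}_reads" for label in FRAGMENT_LABELS]
    return pd.DataFrame(rows, columns=cols)


def merge_events_frame(events: list[MergeEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "absorbed": e.absorbed_id,
                "absorber": e.absorber_id,
                "rule": e.rule,
                "identity": round(e.identity_at_merge, 2) if e.identity_at_merge is not None else "",
            }
            for e in events
        ],
        columns=["absorbed", "absorber", "rule", "identity"],
    )


def sample_qc(
    track: str,
    major_reads: int | None = None,
    trimmed_reads: int | None = None,
    read_floor: int = DEFAULT_READ_FLOOR,
) -> tuple[bool, str]:
    """Sample-level read-support QC.

    Clonal-track samples need strictly more than ``read_floor`` reads on
    the major rearrangement; polyclonal-track samples need at least
    ``read_floor`` trimmed reads.  Failures are reported with a reason,
    never silently dropped.
    """
    if track == "clonal":
        if major_reads is None:
            return False, "no major rearrangement"
        if major_reads > read_floor:
            return True, ""
        return False, f"major rearrangement reads {major_reads} <= {read_floor}"
    if track == "polyclonal":
        if trimmed_reads is None:
            return False, "trimmed read count unavailable"
        if trimmed_reads >= read_floor:
            return True, ""
        return False, f"trimmed reads {trimmed_reads} < {read_floor}"
    raise ValueError(f"unknown QC track {track!r}")
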