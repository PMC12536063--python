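"""Germline IGH V/D/J allele database.

Loads IMGT-style allele FASTA files (headers such as ``>IGHV1-69*09|Homo
sapiens|...`` or ``>IGHJ6*02``), parses allele names into family / gene /
allele fields, and builds the concatenated V--J references against which
rearrangement reads are re-mapped for consensus calling.  The unrepresented
D/junction region between V and J is encoded as a run of ``N`` characters;
its coordinates are returned so downstream code can treat inserted bases
there as the junction sequence.

All coordinates are 0-based, half-open, on the forward strand of the
rearrangement.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: default width of the gap standing in for the D/junction region in a
#: concatenated V-J reference (the region is assembled from reads, not the
#: reference, so the exact width only needs to exceed typical junctions).
DEFAULT_GAP_LEN = 30

# allele token: gene (IGH + segment letter + locus detail) '*' allele number
_ALLELE_RE = re.compile(r"(IGH([VDJ])[A-Za-z0-9./-]*)\*(\d+)")


@dataclass(frozen=True)
class GermlineAllele:
    """One named germline allele, e.g. IGHV1-69*09."""

    name: str
    segment: str  # "V", "D" or "J"
    family: str   # e.g. "IGHV1"
    gene: str     # e.g. "IGHV1-69"
    allele_num: str  # e.g. "09"
    sequence: str    # uppercase A/C/G/T/N

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for allele {self.name}")
        if self.segment not in ("V", "D", "J"):
            raise ValueError(f"bad segment {self.segment!r} for {self.name}")


def parse_allele_name(token: str) -> GermlineAllele | None:
    """Parse an IMGT-style allele token into its name components.

    Returns a sequence-less template (sequence filled by the caller) or
    ``None`` when the token does not contain a recognizable allele name.
    The family is the gene name up to the first ``-`` (e.g. IGHV1-69 ->
    IGHV1); genes without a dash (IGHJ6) are their own family.
    """
    m = _ALLELE_RE.search(token)
    if m is None:
        return None
    gene, segment, allele_num = m.group(1), m.group(2), m.group(3)
    family = gene.split("-", 1)[0]
    return GermlineAllele(
        name=f"{gene}*{allele_num}",
        segment=segment,
        family=family,
        gene=gene,
        allele_num=allele_num,
        sequence="?",  # placeholder; replaced by caller
    )


class GermlineDB:
    """Indexed collection of germline alleles, keyed by allele name."""

    def __init__(self, alleles: Iterable[GermlineAllele] = ()) -> None:
        self.alleles: dict[str, GermlineAllele] = {}
        self.by_segment: dict[str, list[GermlineAllele]] = {"V": [], "D": [], "J": []}
        self.by_gene: dict[str, list[GermlineAllele]] = {}
        self.by_family: dict[str, list[GermlineAllele]] = {}
        for a in alleles:
            self.add(a)

    def add(self, allele: GermlineAllele) -> None:
        if allele.name in self.alleles:
            raise ValueError(f"duplicate allele name {allele.name}")
        self.alleles[allele.name] = allele
        self.by_segment[allele.segment].append(allele)
        self.by_gene.setdefault(allele.gene, []).append(allele)
        self.by_family.setdefault(allele.family, []).append(allele)

    def __len__(self) -> int:
        return len(self.alleles)

    def __contains__(self, name: str) -> bool:
        return name in self.alleles

    def __getitem__(self, name: str) -> GermlineAllele:
        return self.alleles[name]

    def segment(self, segment: str) -> list[GermlineAllele]:
        """All alleles of one segment class, in insertion order."""
        return list(self.by_segment[segment])

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": a.name,
                "segment": a.segment,
                "family": a.family,
                "gene": a.gene,
                "length": len(a.sequence),
            }
            for a in self.alleles.values()
        ]
        return pd.DataFrame(rows, columns=["name", "segment", "family", "gene", "length"])


def load_germline_fasta(path: str | Path) -> GermlineDB:
    """Load a germline allele FASTA into an indexed database.

    The allele name is taken from the first pipe- or whitespace-delimited
    header token that contains ``IGH`` and ``*`` (robust across IMGT
    export dialects).  Records with unparseable headers are skipped and
    counted in a log message; an empty file or a file with zero parseable
    records is a hard error naming the path.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"germline FASTA not found: {path}")
    db = GermlineDB()
    skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        template = None
        for token in re.split(r"[|\s]+", rec.description):
            if "IGH" in token and "*" in token:
                template = parse_allele_name(token)
                if template is not None:
                    break
        if template is None:
            skipped += 1
            continue
        seq = str(rec.seq).upper()
        if not seq:
            skipped += 1
            continue
        db.add(
            GermlineAllele(
                name=template.name,
                segment=template.segment,
                family=template.family,
                gene=template.gene,
                allele_num=template.allele_num,
                sequence=seq,
            )
        )
    if skipped:
        log.warning("skipped %d unparseable germline records in %s", skipped, path)
    if len(db) == 0:
        raise ValueError(f"no parseable germline alleles in {path}")
    return db


def write_germline_fasta(db: GermlineDB, path: str | Path, width: int = 60) -> None:
    """Write the database back to a wrapped multi-line FASTA."""
    records = [
        SeqRecord(Seq(a.sequence), id=a.name, description="")
        for a in db.alleles.values()
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(records)


def concat_vj_reference(
    v: GermlineAllele, j: GermlineAllele, gap_len: int = DEFAULT_GAP_LEN
) -> tuple[str, tuple[int, int]]:
    """Concatenated V-[N gap]-J reference for one V-J pairing.

    Returns the reference string and the half-open 0-based interval of the
    gap; inserted junction bases map inside this interval.
    """
    if v.segment != "V" or j.segment != "J":
        raise ValueError(f"segment mismatch: {v.name} ({v.segment}) / {j.name} ({j.segment})")
    if gap_len < 0:
        raise ValueError("gap_len must be >= 0")
    ref = v.sequence + "N" * gap_len + j.sequence
    gap = (len(v.sequence), len(v.sequence) + gap_len)
    return ref, gap
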