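"""Read preprocessing: end quality trimming and length filtering.

Defaults follow the pipeline contract: trim both ends inward while the
terminal base quality is below Q30, drop reads shorter than 50 bp after
trimming.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

DEFAULT_Q_FLOOR = 30
DEFAULT_MIN_LEN = 50


def quality_trim(
    read: SeqRecord,
    q_floor: int = DEFAULT_Q_FLOOR,
    min_len: int = DEFAULT_MIN_LEN,
    record_index: int | None = None,
) -> SeqRecord | None:
    """Trim low-quality ends; return the trimmed record or None if dropped."""
    quals = read.letter_annotations.get("phred_quality")
    if quals is None or len(quals) != len(read.seq):
        where = f" (record {record_index})" if record_index is not None else ""
        raise ValueError(f"malformed FASTQ record {read.id!r}{where}: quality/sequence length mismatch")
    start, end = 0, len(quals)
    while start < end and quals[start] < q_floor:
        start += 1
    while end > start and quals[end - 1] < q_floor:
        end -= 1
    if end - start < min_len:
        return None
    if start == 0 and end == len(quals):
        return read
    return read[start:end]


def trim_records(
    records: list[SeqRecord],
    q_floor: int = DEFAULT_Q_FLOOR,
    min_len: int = DEFAULT_MIN_LEN,
) -> tuple[list[SeqRecord], dict]:
    """Trim a batch of records; returns kept records and counters."""
    kept: list[SeqRecord] = []
    dropped = 0
    for i, rec in enumerate(records):
        out = quality_trim(rec, q_floor=q_floor, min_len=min_len, record_index=i)
        if out is None:
            dropped += 1
        else:
            kept.append(out)
    return kept, {"input": len(records), "kept": len(kept), "dropped": dropped}


def read_fastq(path: str | Path) -> list[SeqRecord]:
    path = str(path)
    fmt = "fastq"
    if path.endswith(".gz"):
        import gzip

        with gzip.open(path, "rt") as fh:
            return list(SeqIO.parse(fh, fmt))
    return list(SeqIO.parse(path, fmt))
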