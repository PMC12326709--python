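"""FASTQ/FASTA reading and writing via Biopython.

Reads travel through the package as ``(read_id, sequence)`` or
``(read_id, sequence, quality)`` tuples; these helpers convert to and from
files. Output is deterministic byte-for-byte for a fixed input order.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PHRED_I = 40  # 'I' in Phred+33; the simulator emits constant quality


def _record(read_id: str, seq: str, quals: str | None = None) -> SeqRecord:
    rec = SeqRecord(Seq(seq), id=read_id, description="")
    if quals is not None:
        rec.letter_annotations["phred_quality"] = [ord(q) - 33 for q in quals]
    return rec


def write_fastq(reads, path: str | Path) -> None:
    """Write (id, seq[, qual]) tuples as 4-line Phred+33 FASTQ records."""
    records = []
    for tup in reads:
        read_id, seq = tup[0], tup[1]
        quals = tup[2] if len(tup) > 2 else "I" * len(seq)
        records.append(_record(read_id, seq, quals))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def write_fasta(reads, path: str | Path) -> None:
    records = [_record(rid, seq) for rid, seq, *_ in reads]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_bed(intervals, path: str | Path) -> None:
    """Write (chrom, start, end, name, score, strand) rows as BED6."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
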