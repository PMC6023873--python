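"""Readers/writers for the package's external formats.

FASTA/FASTQ go through Biopython; tabular data through pandas.  GFF3 output
is 1-based inclusive per the standard; all internal coordinates are 0-based
half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .repeat_ltr import FullLengthElement, LTRCandidate
from .simulate import PlantedElement


def write_fasta(records: Iterable[tuple[str, str]], path: "str | Path") -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: "str | Path") -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fastq(
    reads: Iterable[tuple[str, str]], path: "str | Path", quality_char: str = "I"
) -> None:
    """Plain FASTQ with constant qualities (the simulator models errors, not
    quality strings)."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path: "str | Path") -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def planted_elements_to_gff3(
    elements: Sequence[PlantedElement], contig: str = "genome"
) -> str:
    """GFF3 (1-based inclusive) for planted LTR elements and their parts."""
    lines = ["##gff-version 3"]
    for e in elements:
        attrs = (
            f"ID={e.element_id};tsd_length={e.tsd_length};"
            f"age_years={e.age_years:g}"
        )
        lines.append(
            f"{contig}\tdodderprint\tLTR_retrotransposon\t{e.start + 1}\t{e.end}"
            f"\t.\t+\t.\t{attrs}"
        )
        for part, s, t in (
            ("five_prime_LTR", e.ltr5_start, e.ltr5_end),
            ("three_prime_LTR", e.ltr3_start, e.ltr3_end),
        ):
            lines.append(
                f"{contig}\tdodderprint\t{part}\t{s + 1}\t{t}\t.\t+\t.\t"
                f"Parent={e.element_id}"
            )
    return "\n".join(lines) + "\n"


def candidates_to_gff3(candidates: Sequence[LTRCandidate]) -> str:
    lines = ["##gff-version 3"]
    for i, c in enumerate(candidates):
        el = c.element
        attrs = (
            f"ID=candidate_{i:05d};ltr_similarity={c.ltr_similarity:.2f};"
            f"tsd_length={c.tsd_length};"
            f"ltr5={c.ltr5.start + 1}-{c.ltr5.end};"
            f"ltr3={c.ltr3.start + 1}-{c.ltr3.end}"
        )
        lines.append(
            f"{el.contig}\tdodderprint\tLTR_retrotransposon\t{el.start + 1}"
            f"\t{el.end}\t.\t{el.strand}\t.\t{attrs}"
        )
    return "\n".join(lines) + "\n"


def elements_to_table(elements: Sequence[FullLengthElement]) -> pd.DataFrame:
    """Dated-element report: one row per element with placement and age."""
    rows = []
    for e in elements:
        rows.append(
            {
                "element_id": e.element_id,
                "contig": e.candidate.element.contig,
                "start": e.candidate.element.start,
                "end": e.candidate.element.end,
                "superfamily": e.superfamily,
                "ltr_similarity": e.candidate.ltr_similarity,
                "divergence": e.divergence,
                "age_years": e.age_years,
            }
        )
    return pd.DataFrame(rows)


def read_hit_table(path: "str | Path") -> pd.DataFrame:
    """12-column tabular homology hits (standard tabular BLAST layout)."""
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    return pd.read_csv(path, sep="\t", names=cols, header=None)
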