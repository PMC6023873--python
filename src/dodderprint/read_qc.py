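"""Mate-pair/fosmid read filtering, position-based deduplication, and
insert-size estimation.

These mirror the preprocessing applied to junction-style jumping libraries:
reads must start with the junction tag, are trimmed at the restriction motif,
duplicate pairs are collapsed on identical mapping coordinates, and insert
sizes are summarised from properly oriented same-contig alignments.
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass
class ReadPair:
    id: str
    forward_seq: str
    reverse_seq: str


@dataclass
class AlignmentRecord:
    """Minimal alignment record (SAM subset) for one mate of a pair."""

    read_id: str
    mate: str            # "forward" | "reverse"
    contig: str
    position: int        # 0-based leftmost
    strand: str          # "+" | "-"
    mapping_quality: int
    length: int = 100    # aligned read length, defines the rightmost end

    @property
    def end(self) -> int:
        return self.position + self.length


def filter_junction_reads(
    pairs: Iterable[ReadPair],
    junction_prefix: str = "CAC",
    restriction_motif: str = "GTAC",
    min_length: int = 20,
) -> tuple[list[ReadPair], Counter]:
    """Junction-tag filter for fosmid/jumping-library pairs.

    A pair is kept only if both mates start with ``junction_prefix``.  Each
    mate is trimmed at the first ``restriction_motif`` occurrence (motif and
    everything downstream removed), and the pair is kept only if both trimmed
    mates are at least ``min_length`` bp.  Rejections are tallied by reason.
    """
    if not junction_prefix or not restriction_motif:
        raise ValueError("motifs must be non-empty")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept: list[ReadPair] = []
    stats: Counter = Counter()

    def trim(seq: str) -> str:
        idx = seq.find(restriction_motif)
        return seq if idx < 0 else seq[:idx]

    for pair in pairs:
        if not (
            pair.forward_seq.startswith(junction_prefix)
            and pair.reverse_seq.startswith(junction_prefix)
        ):
            stats["missing_junction_prefix"] += 1
            continue
        fwd, rev = trim(pair.forward_seq), trim(pair.reverse_seq)
        if len(fwd) < min_length or len(rev) < min_length:
            stats["too_short_after_trim"] += 1
            continue
        kept.append(ReadPair(pair.id, fwd, rev))
        stats["kept"] += 1
    return kept, stats


def deduplicate_pairs(
    alignments: Iterable[AlignmentRecord], min_mapq: int = 3
) -> tuple[list[str], Counter]:
    """Collapse read pairs duplicated at identical mapping positions.

    Pairs with any mate of mapping quality <= ``min_mapq`` are discarded
    (the ambiguity filter is strict: quality must exceed the threshold).
    Among pairs sharing both mates' (contig, position, strand) tuples, the
    first pair by read id is kept.  Orphan mates are excluded and counted.
    Returns the kept read ids, sorted.
    """
    by_read: dict[str, dict[str, AlignmentRecord]] = {}
    for rec in alignments:
        by_read.setdefault(rec.read_id, {})[rec.mate] = rec
    stats: Counter = Counter()
    keyed: dict[tuple, str] = {}
    for read_id in sorted(by_read):
        mates = by_read[read_id]
        if "forward" not in mates or "reverse" not in mates:
            stats["orphan_mate"] += 1
            continue
        f, r = mates["forward"], mates["reverse"]
        if f.mapping_quality <= min_mapq or r.mapping_quality <= min_mapq:
            stats["low_mapping_quality"] += 1
            continue
        key = (f.contig, f.position, f.strand, r.contig, r.position, r.strand)
        if key in keyed:
            stats["duplicate"] += 1
            continue
        keyed[key] = read_id
        stats["kept"] += 1
    return sorted(keyed.values()), stats


@dataclass
class InsertSizeEstimate:
    n_pairs_used: int
    mean: float
    median: float
    sd: float


_ORIENTATIONS = {"fr", "rf", "ff"}


def _orientation_ok(left: AlignmentRecord, right: AlignmentRecord, code: str) -> bool:
    if code == "fr":   # inward: leftmost on +, rightmost on -
        return left.strand == "+" and right.strand == "-"
    if code == "rf":   # outward (jumping-library chemistry)
        return left.strand == "-" and right.strand == "+"
    return left.strand == right.strand  # "ff"


def estimate_insert_sizes(
    alignments: Iterable[AlignmentRecord], expected_orientation: str = "rf"
) -> InsertSizeEstimate:
    """Summarise insert sizes from same-contig pairs in the expected orientation.

    Insert = rightmost alignment end - leftmost alignment start per pair.
    Raises when no pair qualifies.
    """
    if expected_orientation not in _ORIENTATIONS:
        raise ValueError(f"unknown orientation code {expected_orientation!r}")
    by_read: dict[str, dict[str, AlignmentRecord]] = {}
    for rec in alignments:
        by_read.setdefault(rec.read_id, {})[rec.mate] = rec
    inserts: list[int] = []
    for read_id in sorted(by_read):
        mates = by_read[read_id]
        if "forward" not in mates or "reverse" not in mates:
            continue
        f, r = mates["forward"], mates["reverse"]
        if f.contig != r.contig:
            continue
        left, right = (f, r) if f.position <= r.position else (r, f)
        if not _orientation_ok(left, right, expected_orientation):
            continue
        inserts.append(max(f.end, r.end) - min(f.position, r.position))
    if not inserts:
        raise ValueError("no qualifying pairs for insert-size estimation")
    return InsertSizeEstimate(
        n_pairs_used=len(inserts),
        mean=float(statistics.fmean(inserts)),
        median=float(statistics.median(inserts)),
        sd=float(statistics.stdev(inserts)) if len(inserts) > 1 else 0.0,
    )
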