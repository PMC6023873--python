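"""Genome-size estimation from k-mer depth histograms.

The estimator follows the classic shotgun-survey recipe: count canonical
k-mers in unassembled reads, find the local minimum of the depth histogram
that separates sequencing-error k-mers from genomic signal, find the modal
(peak) depth beyond it, and divide the error-filtered k-mer instance total by
the peak depth.  The same k-mer index also drives coverage-based read
selection (e.g. enriching plastid reads, which sit at a far higher depth than
the nuclear background), and two small helpers convert flow-cytometry
fluorescence ratios into 1C values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENCODE[_b] = _i


@dataclass
class KmerHistogram:
    """Distinct-k-mer counts per depth.

    ``counts`` maps depth (>= 1) to the number of distinct canonical k-mers
    observed exactly that many times.
    """

    k: int
    counts: dict[int, int]

    @property
    def distinct_total(self) -> int:
        return sum(self.counts.values())

    @property
    def instances_total(self) -> int:
        return sum(d * c for d, c in self.counts.items())

    def instances_below(self, cutoff: int) -> int:
        """k-mer instances at depth <= cutoff (the error fraction)."""
        return sum(d * c for d, c in self.counts.items() if d <= cutoff)


@dataclass
class GenomeSizeEstimate:
    error_cutoff_depth: int
    peak_depth: int
    instances_total: int
    instances_error: int
    genome_size_bp: int


@dataclass
class FlowCytometrySample:
    """One flow-cytometry measurement against an internal standard.

    The default standard is *Pisum sativum* with 1C = 4.42 pg.
    """

    sample_mean_fi: float
    standard_mean_fi: float
    standard_1c_pg: float = 4.42

    def __post_init__(self) -> None:
        for name in ("sample_mean_fi", "standard_mean_fi", "standard_1c_pg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


class KmerIndex:
    """Canonical k-mer -> depth index over a read set.

    Backed by a sorted array of 2-bit-packed k-mer codes so that per-read
    depth lookups (for coverage-based read selection) stay cheap.
    """

    def __init__(self, k: int, codes: np.ndarray, depths: np.ndarray):
        self.k = k
        self._codes = codes          # sorted unique uint64 canonical codes
        self._depths = depths        # same length, depth per code

    def histogram(self) -> KmerHistogram:
        depth_vals, n_kmers = np.unique(self._depths, return_counts=True)
        return KmerHistogram(
            k=self.k,
            counts={int(d): int(c) for d, c in zip(depth_vals, n_kmers)},
        )

    def depth_of_codes(self, codes: np.ndarray) -> np.ndarray:
        """Depth for each code; 0 for codes never seen."""
        idx = np.searchsorted(self._codes, codes)
        idx = np.minimum(idx, len(self._codes) - 1)
        hit = self._codes[idx] == codes
        out = np.where(hit, self._depths[idx], 0)
        return out.astype(np.int64)

    def mean_read_depth(self, read: str) -> float | None:
        """Mean depth over the read's valid canonical k-mers; None if none."""
        codes = _canonical_codes(read, self.k)
        if codes.size == 0:
            return None
        return float(self.depth_of_codes(codes).mean())


def _encode_bases(seq_bytes: bytes) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq_bytes, dtype=np.uint8)]


def _forward_rc_codes(
    base_codes: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-bit-packed forward and reverse-complement codes for every window,
    plus a validity mask (False where the window touches a non-ACGT base)."""
    n = base_codes.size - k + 1
    if n <= 0:
        empty = np.empty(0, dtype=np.uint64)
        return empty, empty.copy(), np.empty(0, dtype=bool)
    bad = (base_codes >= 4).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (cum[k:] - cum[:-k]) == 0

    b = np.where(base_codes < 4, base_codes, 0).astype(np.uint64)
    comp = (np.uint64(3) - b)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | b[j:j + n]
        rev |= comp[j:j + n] << np.uint64(2 * j)
    return fwd, rev, valid


def _window_codes(base_codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (min of strand encodings) codes for all windows + validity."""
    fwd, rev, valid = _forward_rc_codes(base_codes, k)
    return np.minimum(fwd, rev), valid


def _canonical_codes(seq: str, k: int) -> np.ndarray:
    codes, valid = _window_codes(_encode_bases(seq.encode("ascii")), k)
    return codes[valid]


def build_kmer_index(reads: Iterable[str], k: int) -> KmerIndex:
    """Count canonical k-mers across a read set.

    Reads are concatenated with an ``N`` separator so windows never straddle
    two reads; k-mers containing ambiguous bases are skipped.  The canonical
    form is the lexicographic minimum of the k-mer and its reverse complement
    (equivalently the numeric minimum of their 2-bit encodings).
    """
    if not (1 <= k <= 31) or k % 2 == 0:
        raise ValueError("k must be odd and within 1..31")
    chunks: list[np.ndarray] = []
    n_reads = 0
    # batch reads to bound peak memory while keeping numpy throughput
    batch: list[str] = []
    batch_len = 0

    def flush() -> None:
        nonlocal batch, batch_len
        if not batch:
            return
        blob = "N".join(batch).encode("ascii")
        codes, valid = _window_codes(_encode_bases(blob), k)
        chunks.append(codes[valid])
        batch = []
        batch_len = 0

    for read in reads:
        n_reads += 1
        batch.append(read)
        batch_len += len(read)
        if batch_len >= 8_000_000:
            flush()
    flush()
    if n_reads == 0:
        raise ValueError("empty read set")
    if chunks:
        all_codes = np.concatenate(chunks)
    else:
        all_codes = np.empty(0, dtype=np.uint64)
    codes, depths = np.unique(all_codes, return_counts=True)
    return KmerIndex(k, codes, depths.astype(np.int64))


def count_kmers(reads: Iterable[str], k: int) -> KmerHistogram:
    """Canonical k-mer depth histogram of a read set (see build_kmer_index)."""
    return build_kmer_index(reads, k).histogram()


def _smoothed_sparse(hist: KmerHistogram) -> tuple[np.ndarray, np.ndarray]:
    """Window-3 centered moving average over the observed depth bins."""
    depths = np.array(sorted(hist.counts), dtype=np.int64)
    counts = np.array([hist.counts[int(d)] for d in depths], dtype=float)
    smoothed = np.empty_like(counts)
    for i in range(counts.size):
        lo, hi = max(0, i - 1), min(counts.size, i + 2)
        smoothed[i] = counts[lo:hi].mean()
    return depths, smoothed


def find_error_minimum(hist: KmerHistogram) -> int:
    """Valley separating the error peak from the genomic signal.

    Returns the first depth into which the (window-3 smoothed) distinct-count
    curve strictly decreases all the way from its lowest bin and after which
    it increases — i.e. the valley right of the sequencing-error peak at
    depth 1.  Low-depth k-mers up to and including this depth are classed as
    error products.  Raises when the curve does not start by decreasing or
    never turns back up (no error/signal separation), which is what
    error-free reads produce.
    """
    if len(hist.counts) < 3:
        raise ValueError("histogram needs at least 3 depth bins")
    depths, smoothed = _smoothed_sparse(hist)
    for i in range(1, smoothed.size - 1):
        if smoothed[i] >= smoothed[i - 1]:
            break  # the descent from the error peak has ended
        if smoothed[i + 1] > smoothed[i]:
            return int(depths[i])
    raise ValueError("no error/signal separation in k-mer histogram")


def find_peak(hist: KmerHistogram, error_cutoff: int) -> int:
    """Modal depth (argmax of distinct-k-mer counts) beyond the error cutoff.

    Ties break toward the lower depth, which is the conservative choice for
    the size estimate.
    """
    best_depth, best_count = None, -1
    for d in sorted(hist.counts):
        if d <= error_cutoff:
            continue
        c = hist.counts[d]
        if c > best_count:
            best_depth, best_count = d, c
    if best_depth is None:
        raise ValueError("no depth beyond the error cutoff")
    return best_depth


def estimate_genome_size(
    hist: KmerHistogram, error_cutoff: int | None = None
) -> GenomeSizeEstimate:
    """Error-filtered k-mer instances divided by the peak depth.

    With ``error_cutoff=None`` the cutoff is detected automatically from the
    histogram valley; pass ``0`` explicitly for error-free data, where no
    valley exists and nothing should be subtracted.
    """
    if error_cutoff is None:
        error_cutoff = find_error_minimum(hist)
    peak = find_peak(hist, error_cutoff)
    total = hist.instances_total
    err = hist.instances_below(error_cutoff)
    size = int(round((total - err) / peak))
    return GenomeSizeEstimate(
        error_cutoff_depth=error_cutoff,
        peak_depth=peak,
        instances_total=total,
        instances_error=err,
        genome_size_bp=size,
    )


def select_high_coverage_pairs(
    pairs: Sequence[tuple[str, str, str]],
    index: KmerIndex,
    threshold: float,
) -> list[tuple[str, str, str]]:
    """Keep read pairs whose mean k-mer depth exceeds ``threshold`` on both mates.

    ``pairs`` are (pair_id, forward_seq, reverse_seq) tuples.  The comparison
    is strict (> threshold), so organelle reads sitting at multi-hundred-fold
    depth pass while single-copy nuclear reads do not.  Pairs in which a mate
    has no valid k-mer are dropped with a warning.  Input order is preserved.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    kept = []
    for pair_id, fwd, rev in pairs:
        mean_f = index.mean_read_depth(fwd)
        mean_r = index.mean_read_depth(rev)
        if mean_f is None or mean_r is None:
            logger.warning("pair %s dropped: mate without valid k-mers", pair_id)
            continue
        if mean_f > threshold and mean_r > threshold:
            kept.append((pair_id, fwd, rev))
    return kept


def flow_1c(sample: FlowCytometrySample) -> float:
    """1C DNA amount in pg from a fluorescence ratio against the standard."""
    return sample.sample_mean_fi / sample.standard_mean_fi * sample.standard_1c_pg


def pg_to_mbp(mass_pg: float, factor: float = 978.0) -> float:
    """Convert picograms of DNA to megabase pairs (978 Mbp per pg)."""
    if factor <= 0:
        raise ValueError("conversion factor must be positive")
    if mass_pg < 0:
        raise ValueError("mass must be non-negative")
    return mass_pg * factor
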