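"""Full-length LTR retrotransposon detection, filtering, classification,
clustering, and insertion dating.

The two long terminal repeats of an element are identical at insertion, so
their subsequent divergence, divided by twice the neutral mutation rate,
dates the insertion event.  Detection here is a structural search tuned to
the no-indel synthetic genomes this package simulates: exact seed k-mers
shared at a direct-repeat offset within the allowed LTR distance window are
chained on their diagonal, extended ungapped with an x-drop rule, and the
boundaries are then snapped to the TG...CA terminal motif plus an exact
4-20 bp target-site duplication.
"""

from __future__ import annotations

import math
from bisect import insort
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np
from Bio import Align

from .genome_size import _encode_bases, _forward_rc_codes

DEFAULT_MUTATION_RATE = 7e-9  # substitutions / site / year


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class LibraryMatch:
    """A scored homology match of a repeat-library entry on the genome."""

    location: Interval
    library_id: str
    score: float
    identity: float = 100.0


@dataclass
class LTRCandidate:
    element: Interval
    ltr5: Interval
    ltr3: Interval
    tsd_length: int
    motif_ok: bool
    ltr_similarity: float  # percent identity between the two LTR copies


@dataclass
class DomainAnnotation:
    element_id: str
    domain: str        # GAG / INT / RT / RH / PBS / gene / other
    order_index: int   # 5'->3' position on the element
    strand: str        # "+" | "-"


@dataclass
class FullLengthElement:
    element_id: str
    candidate: LTRCandidate
    domains: list[DomainAnnotation] = field(default_factory=list)
    tandem_fraction: float = 0.0
    n_fraction: float = 0.0
    superfamily: str = "unknown"
    divergence: float | None = None
    age_years: float | None = None
    sequence: str | None = None


@dataclass
class LTRParams:
    """Structural constraints for candidate detection."""

    min_ltr: int = 100
    max_ltr: int = 2000
    min_dist: int = 3000       # 5' LTR start to 3' LTR start
    max_dist: int = 25000
    min_similarity: float = 85.0
    min_tsd: int = 4
    max_tsd: int = 20
    motif_mismatch: int = 1    # TG...CA, total allowed mismatches
    seed_length: int = 20
    vicinity: int = 60
    xdrop: int = 20


# ---------------------------------------------------------------------------
# overlap resolution of repeat-library matches


def _uncovered_segments(
    start: int, end: int, accepted: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Parts of [start, end) not covered by the sorted accepted intervals."""
    segs: list[tuple[int, int]] = []
    cursor = start
    for a, b in accepted:
        if b <= start or a >= end:
            continue
        if a > cursor:
            segs.append((cursor, min(a, end)))
        cursor = max(cursor, b)
        if cursor >= end:
            break
    if cursor < end:
        segs.append((cursor, end))
    return segs


def resolve_overlaps(
    matches: Iterable[LibraryMatch],
    coverage_threshold: float = 90.0,
    min_rest: int = 50,
) -> list[LibraryMatch]:
    """Priority-based resolution of overlapping repeat matches.

    Matches are placed in descending score order (ties: longer first, then
    coordinate).  A lower-scoring match overlapped by already-accepted ones
    is trimmed to its longest uncovered remainder when the accepted overlap
    covers less than ``coverage_threshold`` percent of it and that remainder
    is at least ``min_rest`` bp; otherwise it is removed.  The result is an
    overlap-free annotation.
    """
    ordered = sorted(
        matches,
        key=lambda m: (-m.score, -m.location.length, m.location.contig,
                       m.location.start),
    )
    accepted_by_contig: dict[str, list[tuple[int, int]]] = defaultdict(list)
    out: list[LibraryMatch] = []
    for m in ordered:
        loc = m.location
        accepted = accepted_by_contig[loc.contig]
        segs = _uncovered_segments(loc.start, loc.end, accepted)
        uncovered = sum(b - a for a, b in segs)
        covered_pct = 100.0 * (loc.length - uncovered) / loc.length
        if uncovered == loc.length:
            keep = loc
        else:
            if covered_pct >= coverage_threshold:
                continue
            best = max(segs, key=lambda s: (s[1] - s[0], -s[0]), default=None)
            if best is None or best[1] - best[0] < min_rest:
                continue
            keep = Interval(loc.contig, best[0], best[1], loc.strand)
        insort(accepted, (keep.start, keep.end))
        out.append(LibraryMatch(keep, m.library_id, m.score, m.identity))
    out.sort(key=lambda m: (m.location.contig, m.location.start))
    return out


# ---------------------------------------------------------------------------
# structural candidate detection


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _seed_pairs(genome: str, params: LTRParams) -> dict[int, list[int]]:
    """Positions of exact seed matches at direct-repeat offsets, by offset."""
    k = params.seed_length
    base = _encode_bases(genome.encode("ascii"))
    fwd, _, valid = _forward_rc_codes(base, k)
    pos = np.nonzero(valid)[0]
    codes = fwd[valid]
    order = np.argsort(codes, kind="stable")
    codes, pos = codes[order], pos[order]
    by_offset: dict[int, list[int]] = defaultdict(list)
    n = codes.size
    i = 0
    while i < n:
        j = i + 1
        while j < n and codes[j] == codes[i]:
            j += 1
        if 2 <= j - i <= 12:  # skip high-copy k-mers
            group = np.sort(pos[i:j])
            for a in range(len(group)):
                for b in range(a + 1, len(group)):
                    off = int(group[b] - group[a])
                    if params.min_dist <= off <= params.max_dist:
                        by_offset[off].append(int(group[a]))
        i = j
    return by_offset


def _extend_diagonal(
    genome: str, start: int, end: int, offset: int, params: LTRParams
) -> tuple[int, int]:
    """Ungapped x-drop extension of a seed chain along its diagonal.

    Returns the extended half-open span on the 5' copy.
    """
    g = len(genome)

    def run(begin: int, step: int) -> int:
        score, best, best_i = 0, 0, begin - step
        i = begin
        while 0 <= i and i + offset < g and 0 <= i + offset:
            score += 2 if genome[i] == genome[i + offset] else -2
            if score > best:
                best, best_i = score, i
            elif best - score > params.xdrop:
                break
            i += step
        return best_i

    left = run(start - 1, -1)
    right = run(end, +1)
    lo = left + 1 if left < start else start
    hi = right + 1 if right >= end else end
    return lo, hi


def _find_tsd(genome: str, el_start: int, el_end: int, params: LTRParams) -> int | None:
    """Longest exact target-site duplication flanking [el_start, el_end)."""
    for t in range(params.max_tsd, params.min_tsd - 1, -1):
        if el_start - t < 0 or el_end + t > len(genome):
            continue
        if genome[el_start - t:el_start] == genome[el_end:el_end + t]:
            return t
    return None


def _refine_boundaries(
    genome: str, lo: int, hi: int, offset: int, params: LTRParams
) -> tuple[int, int, int] | None:
    """Snap the extended diagonal span to motif + TSD boundaries.

    Returns (ltr_start, ltr_end, tsd_length) on the 5' copy, or None.
    """
    g = len(genome)
    vic = params.vicinity
    s_opts = []
    for s in range(max(0, lo - vic), min(g, lo + vic + 1)):
        mism = _hamming(genome[s:s + 2], "TG")
        if mism <= params.motif_mismatch:
            s_opts.append((abs(s - lo), s, mism))
    e_opts = []
    for e in range(max(2, hi - vic), min(g - offset, hi + vic) + 1):
        tail = genome[e + offset - 2:e + offset]
        mism = _hamming(tail, "CA")
        if mism <= params.motif_mismatch:
            e_opts.append((abs(e - hi), e, mism))
    s_opts.sort()
    e_opts.sort()
    # A boundary shifted into the TSD can still exhibit an exact (often
    # phase-shifted) duplication, so closeness alone is unreliable: rank
    # passing pairs by motif exactness, then TSD length, then closeness.
    best: tuple[int, int, int, int, int] | None = None
    for ds, s, ms in s_opts:
        for de, e, me in e_opts:
            if ms + me > params.motif_mismatch:
                continue
            ltr_len = e - s
            if not params.min_ltr <= ltr_len <= params.max_ltr:
                continue
            tsd = _find_tsd(genome, s, e + offset, params)
            if tsd is None:
                continue
            key = (ms + me, -tsd, ds + de, s, e)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    return best[3], best[4], -best[1]


def detect_ltr_candidates(
    genome: str,
    params: LTRParams | None = None,
    contig: str = "genome",
) -> list[LTRCandidate]:
    """Structural search for full-length LTR retrotransposon candidates.

    Every reported candidate satisfies all constraints (LTR length, LTR
    distance, similarity, TSD, terminal motif); overlapping candidates are
    resolved higher-similarity-first.
    """
    params = params or LTRParams()
    if len(genome) < params.min_dist + 2:
        return []
    by_offset = _seed_pairs(genome, params)
    raw: list[LTRCandidate] = []
    seen: set[tuple[int, int, int]] = set()
    for offset, positions in sorted(by_offset.items()):
        positions = sorted(positions)
        clusters: list[list[int]] = [[positions[0]]]
        for p in positions[1:]:
            if p - clusters[-1][-1] <= 500:
                clusters[-1].append(p)
            else:
                clusters.append([p])
        for cl in clusters:
            lo, hi = _extend_diagonal(
                genome, cl[0], cl[-1] + params.seed_length, offset, params
            )
            refined = _refine_boundaries(genome, lo, hi, offset, params)
            if refined is None:
                continue
            s, e, tsd = refined
            if (s, e, offset) in seen:
                continue
            seen.add((s, e, offset))
            ltr_len = e - s
            mism = _hamming(genome[s:e], genome[s + offset:e + offset])
            similarity = 100.0 * (1.0 - mism / ltr_len)
            if similarity < params.min_similarity:
                continue
            raw.append(
                LTRCandidate(
                    element=Interval(contig, s, e + offset, "+"),
                    ltr5=Interval(contig, s, e, "+"),
                    ltr3=Interval(contig, s + offset, e + offset, "+"),
                    tsd_length=tsd,
                    motif_ok=True,
                    ltr_similarity=similarity,
                )
            )
    raw.sort(key=lambda c: (-c.ltr_similarity, c.element.start))
    accepted: list[LTRCandidate] = []
    for cand in raw:
        if not any(cand.element.overlaps(a.element) for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda c: c.element.start)
    return accepted


# ---------------------------------------------------------------------------
# the seven-criterion false-positive filter

_CORE_DOMAINS = {"GAG", "INT", "RT", "RH"}


def filter_full_length(element: FullLengthElement) -> tuple[bool, list[int]]:
    """Apply the seven-criterion false-positive filter.

    1. at least one typical retrotransposon domain (RT, RH, INT, GAG);
    2. no hybrid domain mixes (a core domain appearing more than once);
    3. no gene (host-protein) domains;
    4. strand consistency across domains and the primer binding site;
    5. tandem-repeat content below 25%;
    6. each LTR at most 25% of the element length;
    7. N content below 5%.
    """
    failed: list[int] = []
    domains = element.domains
    core = [d for d in domains if d.domain in _CORE_DOMAINS]
    if not core:
        failed.append(1)
    counts = Counter(d.domain for d in core)
    if any(c > 1 for c in counts.values()):
        failed.append(2)
    if any(d.domain == "gene" for d in domains):
        failed.append(3)
    if len({d.strand for d in domains}) > 1:
        failed.append(4)
    if element.tandem_fraction >= 0.25:
        failed.append(5)
    el_len = element.candidate.element.length
    if (
        element.candidate.ltr5.length > 0.25 * el_len
        or element.candidate.ltr3.length > 0.25 * el_len
    ):
        failed.append(6)
    if element.n_fraction >= 0.05:
        failed.append(7)
    return (not failed), failed


def classify_superfamily(domains: Sequence[DomainAnnotation]) -> str:
    """Ty3/gypsy vs Ty1/copia from the inner domain order.

    Only the INT/RT/RH order matters (GAG and PBS placement is ignored);
    missing INT or RT yields ``unknown``.  Minus-strand elements are read
    3'->5'.
    """
    ordered = sorted(domains, key=lambda d: d.order_index)
    if ordered and all(d.strand == "-" for d in ordered):
        ordered = ordered[::-1]
    core = [d.domain for d in ordered if d.domain in {"INT", "RT", "RH"}]
    if "INT" not in core or "RT" not in core:
        return "unknown"
    if core == ["RT", "RH", "INT"]:
        return "Ty3_gypsy"
    if core == ["INT", "RT", "RH"]:
        return "Ty1_copia"
    return "unknown"


# ---------------------------------------------------------------------------
# redundancy clustering


def cluster_elements(
    elements: Sequence[FullLengthElement],
    min_identity: float = 95.0,
    min_coverage: float = 95.0,
) -> list[FullLengthElement]:
    """Single-linkage clustering to a non-redundant representative set.

    Two elements are linked when their global-alignment identity exceeds
    ``min_identity`` percent over more than ``min_coverage`` percent mutual
    length coverage.  Each cluster is represented by its longest element
    (ties by id).
    """
    n = len(elements)
    seqs = []
    for e in elements:
        if e.sequence is None:
            raise ValueError(f"element {e.element_id} lacks a sequence")
        seqs.append(e.sequence)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            la, lb = len(seqs[i]), len(seqs[j])
            if 100.0 * min(la, lb) / max(la, lb) <= min_coverage:
                continue
            dist = edlib.align(seqs[i], seqs[j], mode="NW", task="distance")[
                "editDistance"
            ]
            identity = 100.0 * (1.0 - dist / max(la, lb))
            if identity > min_identity:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        clusters[find(i)].append(i)
    reps = []
    for members in clusters.values():
        best = min(members, key=lambda i: (-len(seqs[i]), elements[i].element_id))
        reps.append(elements[best])
    reps.sort(key=lambda e: e.element_id)
    return reps


# ---------------------------------------------------------------------------
# dating

# Gap costs are deliberately stiff: with cheap gaps (e.g. open/extend -3) the
# optimal alignment hides clustered mismatches behind paired gaps, deflating
# the p-distance by several percent at LTR divergences above ~5% and biasing
# every downstream insertion age young.
_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 2
_aligner.mismatch_score = -2
_aligner.open_gap_score = -10
_aligner.extend_gap_score = -5


def ltr_divergence(
    ltr5_seq: str, ltr3_seq: str, jukes_cantor: bool = False
) -> float:
    """Divergence between the two LTR copies of one element.

    Global alignment; divergence is mismatched columns over aligned non-gap
    columns (raw p-distance by default, Jukes-Cantor corrected on request).
    Raises when the aligned fraction is under 50% of the shorter sequence.
    """
    if len(ltr5_seq) < 50 or len(ltr3_seq) < 50:
        raise ValueError("LTR sequences must be at least 50 bp")
    alignment = _aligner.align(ltr5_seq, ltr3_seq)[0]
    blocks_a, blocks_b = alignment.aligned
    aligned_cols = 0
    mismatches = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        aligned_cols += a1 - a0
        mismatches += _hamming(ltr5_seq[a0:a1], ltr3_seq[b0:b1])
    if aligned_cols < 0.5 * min(len(ltr5_seq), len(ltr3_seq)):
        raise ValueError("sequences not homologous (alignment coverage < 50%)")
    p = mismatches / aligned_cols
    if not jukes_cantor:
        return p
    if p >= 0.75:
        raise ValueError("p-distance saturated; Jukes-Cantor correction undefined")
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def date_insertion(
    divergence: float, mutation_rate: float = DEFAULT_MUTATION_RATE
) -> float:
    """Insertion age in years: divergence / (2 x mutation rate)."""
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    if mutation_rate <= 0:
        raise ValueError("mutation_rate must be > 0")
    return divergence / (2.0 * mutation_rate)


def age_histogram(
    elements: Sequence[FullLengthElement],
    bin_width: float,
    by_superfamily: bool = False,
) -> tuple[np.ndarray, "np.ndarray | dict[str, np.ndarray]"]:
    """Counts of dated elements per insertion-age bin.

    Returns (bin_edges, counts); with ``by_superfamily`` the counts are a
    dict keyed by superfamily label over the shared edges.
    """
    ages = [e.age_years for e in elements]
    if any(a is None for a in ages):
        raise ValueError("all elements must be dated")
    ages_arr = np.asarray(ages, dtype=float)
    top = max(ages_arr.max(), bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    if edges[-1] < top:
        edges = np.append(edges, edges[-1] + bin_width)
    if not by_superfamily:
        counts, _ = np.histogram(ages_arr, bins=edges)
        return edges, counts
    out: dict[str, np.ndarray] = {}
    for sf in sorted({e.superfamily for e in elements}):
        sub = np.asarray([e.age_years for e in elements if e.superfamily == sf])
        out[sf], _ = np.histogram(sub, bins=edges)
    return edges, out
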