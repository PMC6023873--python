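"""Genetic-code helpers shared by the dS estimator and the paralog simulator.

Universal (standard) code only.  Site fractions follow the Nei–Gojobori (1986)
convention: for each codon position the three possible single-nucleotide
changes are classed synonymous iff the encoded amino acid is unchanged;
changes that create a stop codon count as nonsynonymous.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

ALL_CODONS = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon, '*' for a stop."""
    return "*" if codon in STOP_CODONS else CODON_TABLE[codon]


@lru_cache(maxsize=None)
def synonymous_site_fraction(codon: str) -> float:
    """Number of synonymous sites in ``codon`` (0..3) under NG86 counting.

    Each position contributes (synonymous changes among the 3 alternatives)/3.
    Mutations to stop codons are nonsynonymous.  Stop codons themselves have
    no defined site count and raise.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"site counting undefined for stop codon {codon}")
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt not in STOP_CODONS and CODON_TABLE[alt] == aa:
                s += 1.0
    return s / 3.0


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Averaged over all orderings of the differing positions; pathways passing
    through a stop-codon intermediate are excluded (if every pathway does,
    the average falls back to the unrestricted set).
    """
    if codon_a in STOP_CODONS or codon_b in STOP_CODONS:
        raise ValueError("difference counting undefined for stop codons")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        syn = non = 0.0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                if not allow_stops:
                    return None
                non += 1.0  # step through a stop counts as nonsynonymous
            elif translate_codon(current) == translate_codon(nxt):
                syn += 1.0
            else:
                non += 1.0
            current = nxt
        return syn, non

    orders = list(permutations(diff_pos))
    tallies = [t for o in orders if (t := walk(o, allow_stops=False)) is not None]
    if not tallies:
        tallies = [walk(o, allow_stops=True) for o in orders]
    syn = sum(t[0] for t in tallies) / len(tallies)
    non = sum(t[1] for t in tallies) / len(tallies)
    return syn, non


@lru_cache(maxsize=None)
def synonymous_alternatives(codon: str) -> tuple[str, ...]:
    """Sense codons one substitution away that encode the same amino acid."""
    aa = translate_codon(codon)
    out = []
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt not in STOP_CODONS and CODON_TABLE[alt] == aa:
                out.append(alt)
    return tuple(out)
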