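"""Synonymous substitution rates and whole-genome-duplication peak detection.

Protein alignments are backtranslated to codon alignments, pairwise dS is
estimated with the Nei-Gojobori (1986) counting method under a Jukes-Cantor
multiple-hit correction, and the mode of the dS distribution across many
pairs is located by kernel density estimation.  A recent WGD shows up as a
low-dS paralog peak sitting well below the ortholog peaks against related
species.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from ._codon import (
    STOP_CODONS,
    pathway_differences,
    synonymous_site_fraction,
    translate_codon,
)

logger = logging.getLogger(__name__)

_GAP_CODON = "---"


@dataclass
class DsResult:
    syn_sites: float       # S
    nonsyn_sites: float    # N
    syn_diffs: float       # Sd
    nonsyn_diffs: float    # Nd
    ps: float
    pn: float
    ds: float              # nan when saturated
    dn: float
    n_codons_used: int
    saturated_s: bool = False
    saturated_n: bool = False


def backtranslate_alignment(
    protein_alignment: tuple[str, str], cds: tuple[str, str]
) -> tuple[str, str]:
    """Replace each aligned amino acid by its source codon, gaps by ``---``.

    Each CDS must translate exactly (standard code) to its ungapped protein;
    a terminal stop codon on the CDS is tolerated and dropped.  Mismatches
    raise with the offending protein position.
    """
    out = []
    for prot, cds_seq in zip(protein_alignment, cds):
        residues = prot.replace("-", "")
        cds_seq = cds_seq.upper()
        if len(cds_seq) == 3 * (len(residues) + 1) and cds_seq[-3:] in STOP_CODONS:
            cds_seq = cds_seq[:-3]
        if len(cds_seq) != 3 * len(residues):
            raise ValueError(
                f"CDS length {len(cds_seq)} does not match "
                f"{len(residues)} aligned residues"
            )
        codons = [cds_seq[i:i + 3] for i in range(0, len(cds_seq), 3)]
        for idx, (aa, codon) in enumerate(zip(residues, codons)):
            if translate_codon(codon) != aa:
                raise ValueError(
                    f"translation mismatch at protein position {idx}: "
                    f"codon {codon} is {translate_codon(codon)}, expected {aa}"
                )
        it = iter(codons)
        out.append("".join(_GAP_CODON if aa == "-" else next(it) for aa in prot))
    return out[0], out[1]


def _codon_columns(aln_a: str, aln_b: str) -> list[tuple[str, str]]:
    if len(aln_a) != len(aln_b) or len(aln_a) % 3:
        raise ValueError("codon alignments must have equal length divisible by 3")
    cols = []
    n_stop = 0
    for i in range(0, len(aln_a), 3):
        ca, cb = aln_a[i:i + 3], aln_b[i:i + 3]
        if "-" in ca or "-" in cb:
            continue
        if any(base not in "ACGT" for base in ca + cb):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            n_stop += 1
            continue
        cols.append((ca, cb))
    if n_stop:
        logger.warning("dropped %d stop-containing codon columns", n_stop)
    return cols


def _jc(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return math.nan, True
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p), False


def estimate_ds(alignment: tuple[str, str]) -> DsResult:
    """Nei-Gojobori (1986) dS/dN for one pairwise codon alignment.

    Synonymous/nonsynonymous site counts are averaged over both sequences;
    differences in multi-hit codons are averaged over all minimal mutational
    pathways (stop-codon intermediates excluded).  The Jukes-Cantor
    correction is applied to the difference proportions; a proportion at or
    beyond 3/4 is flagged saturated and the rate set to NaN.
    """
    aln_a, aln_b = alignment
    cols = _codon_columns(aln_a.upper(), aln_b.upper())
    if len(cols) < 10:
        raise ValueError(
            f"only {len(cols)} comparable codon pairs after gap/stop removal; "
            "need at least 10"
        )
    s_a = sum(synonymous_site_fraction(ca) for ca, _ in cols)
    s_b = sum(synonymous_site_fraction(cb) for _, cb in cols)
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * len(cols) - s_sites
    sd = nd = 0.0
    for ca, cb in cols:
        d_s, d_n = pathway_differences(ca, cb)
        sd += d_s
        nd += d_n
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    ds, sat_s = _jc(ps)
    dn, sat_n = _jc(pn)
    return DsResult(
        syn_sites=s_sites,
        nonsyn_sites=n_sites,
        syn_diffs=sd,
        nonsyn_diffs=nd,
        ps=ps,
        pn=pn,
        ds=ds,
        dn=dn,
        n_codons_used=len(cols),
        saturated_s=sat_s,
        saturated_n=sat_n,
    )


def select_pairs(
    matrix: pd.DataFrame,
    genes: Mapping[tuple[str, str], Sequence[str]],
    mode: str,
    focal: str = "focal",
    other_species: str | None = None,
) -> list[tuple[str, str]]:
    """Gene pairs for dS estimation from an orthogroup count matrix.

    ``paralog`` mode: the two focal genes of orthogroups with exactly two
    focal members.  ``ortholog-1to1`` mode: (focal, other) gene pairs from
    orthogroups with exactly one gene in each of the two species.  ``genes``
    maps (orthogroup, species) to that cell's gene ids.
    """
    pairs: list[tuple[str, str]] = []
    if mode == "paralog":
        for og in matrix.index[matrix[focal] == 2]:
            members = list(genes.get((og, focal), ()))
            if len(members) == 2:
                pairs.append((members[0], members[1]))
    elif mode == "ortholog-1to1":
        if other_species is None:
            raise ValueError("ortholog-1to1 mode requires other_species")
        sel = (matrix[focal] == 1) & (matrix[other_species] == 1)
        for og in matrix.index[sel]:
            a = list(genes.get((og, focal), ()))
            b = list(genes.get((og, other_species), ()))
            if len(a) == 1 and len(b) == 1:
                pairs.append((a[0], b[0]))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pairs


def ds_peak(values, bandwidth: float | None = None, grid_size: int = 512) -> float:
    """Mode of a dS distribution by Gaussian kernel density estimation.

    Non-finite (saturated) values are excluded; at least 30 finite values
    are required (use a histogram for fewer).  The density is evaluated on a
    regular grid over [0, max(values)]; ``bandwidth`` is an absolute kernel
    width, defaulting to Silverman's rule.
    """
    vals = np.asarray(list(values), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 30:
        raise ValueError(
            f"only {vals.size} finite dS values; need >= 30 for a KDE peak "
            "(consider a histogram instead)"
        )
    if np.ptp(vals) == 0:
        return float(vals[0])
    if bandwidth is None:
        kde = gaussian_kde(vals, bw_method="silverman")
    else:
        kde = gaussian_kde(vals, bw_method=bandwidth / vals.std(ddof=1))
    grid = np.linspace(0.0, vals.max(), grid_size)
    return float(grid[np.argmax(kde(grid))])
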