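"""Orthogroup copy-number dynamics and functional enrichment.

Classifies orthogroups into loss/duplication/single-copy classes relative to
a focal species, calls presence/absence from homology score tables, and
tests functional-category enrichment with Fisher's exact test under
Benjamini-Yekutieli FDR control (valid under arbitrary dependence).
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from math import comb
from typing import Mapping

import numpy as np
import pandas as pd

LABELS = (
    "single_copy_universal",
    "loss_strict",
    "loss_broad",
    "dup_exact",
    "dup_ratio",
    "other",
)


def classify_orthogroups(matrix: pd.DataFrame, focal: str = "focal") -> pd.Series:
    """Copy-number class per orthogroup, relative to the focal species.

    Classes (checked in this precedence, strict before broad):

    * ``single_copy_universal`` - every species has exactly one gene;
    * ``loss_strict``  - focal 0, every other species exactly 1;
    * ``loss_broad``   - focal 0, every other species >= 1;
    * ``dup_exact``    - focal 2, every other species exactly 1;
    * ``dup_ratio``    - every species >= 1 and focal >= 2x the count of
      every other species;
    * ``other``        - anything else.
    """
    if focal not in matrix.columns:
        raise ValueError(f"focal species {focal!r} not in matrix columns")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 species")
    f = matrix[focal].to_numpy()
    others = matrix.drop(columns=[focal]).to_numpy()
    all_one = (others == 1).all(axis=1)
    all_ge1 = (others >= 1).all(axis=1)
    out = np.full(matrix.shape[0], "other", dtype=object)
    dup_ratio = (f >= 1) & all_ge1 & (f[:, None] >= 2 * others).all(axis=1)
    out[dup_ratio] = "dup_ratio"
    out[(f == 2) & all_one] = "dup_exact"
    out[(f == 0) & all_ge1] = "loss_broad"
    out[(f == 0) & all_one] = "loss_strict"
    out[(f == 1) & all_one] = "single_copy_universal"
    return pd.Series(out, index=matrix.index, name="class")


def presence_calls(scores: pd.DataFrame, threshold: float = 50.0) -> pd.DataFrame:
    """Presence/absence from best homology scores: present iff score > threshold.

    Missing entries (NaN) are absences.
    """
    return scores.gt(threshold).fillna(False).astype(bool)


@lru_cache(maxsize=100_000)
def _hypergeom_pmfs(row1: int, row2: int, col1: int) -> tuple[tuple[int, Fraction], ...]:
    """Exact pmf of the 2x2-table support for fixed margins, as Fractions."""
    total = row1 + row2
    denom = comb(total, col1)
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    return tuple(
        (x, Fraction(comb(row1, x) * comb(row2, col1 - x), denom))
        for x in range(lo, hi + 1)
    )


_TIE_SLACK = Fraction(10_000_001, 10_000_000)  # 1 + 1e-7, the R/scipy convention


def fisher_exact_p(
    a: int, b: int, c: int, d: int, alternative: str = "two-sided"
) -> float:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Computed by exact rational hypergeometric summation.  Two-sided: sum of
    the probabilities of all tables (same margins) no more probable than the
    observed one, with the conventional 1+1e-7 relative tie slack.
    ``greater`` tests enrichment of cell ``a``.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    pmfs = _hypergeom_pmfs(a + b, c + d, a + c)
    obs = dict(pmfs)[a]
    if alternative == "two-sided":
        p = sum(pr for _, pr in pmfs if pr <= obs * _TIE_SLACK)
    elif alternative == "greater":
        p = sum(pr for x, pr in pmfs if x >= a)
    elif alternative == "less":
        p = sum(pr for x, pr in pmfs if x <= a)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(p, Fraction(1)))


def by_fdr(pvalues) -> np.ndarray:
    """Benjamini-Yekutieli adjusted values, input order preserved.

    q_(i) = min_{j >= i} p_(j) * m * c(m) / j with c(m) the harmonic sum;
    capped at 1.  Valid under arbitrary dependence between the tests.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def fisher_enrichment(
    labels: Mapping[str, str] | pd.Series,
    annotation: Mapping[str, "set[str] | frozenset[str]"],
    target_label: str,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Functional-category enrichment of a copy-number class.

    For every annotation bin a 2x2 table is built over the annotated items
    (in-bin vs not x target-label vs not): ``a`` counts in-bin targets.
    Items without any annotation are excluded (the count is recorded in
    ``DataFrame.attrs['n_unannotated']``).  Rows are sorted by p; ``q`` holds
    Benjamini-Yekutieli adjusted values.
    """
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    annotated = {k: v for k, v in labels.items() if annotation.get(k)}
    n_unannotated = len(labels) - len(annotated)
    bins: dict[str, set[str]] = {}
    for item in annotated:
        for b in annotation[item]:
            bins.setdefault(b, set()).add(item)
    total = len(annotated)
    n_target = sum(1 for v in annotated.values() if v == target_label)
    rows = []
    for b in sorted(bins):
        members = bins[b]
        if not members:
            continue
        a = sum(1 for i in members if annotated[i] == target_label)
        b_cnt = len(members) - a
        c = n_target - a
        d = total - len(members) - c
        rows.append(
            {
                "bin": b,
                "a": a,
                "b": b_cnt,
                "c": c,
                "d": d,
                "p": fisher_exact_p(a, b_cnt, c, d, alternative=alternative),
            }
        )
    result = pd.DataFrame(rows, columns=["bin", "a", "b", "c", "d", "p"])
    if len(result):
        result["q"] = by_fdr(result["p"].to_numpy())
        result = result.sort_values(["p", "bin"], kind="stable").reset_index(drop=True)
    else:
        result["q"] = pd.Series(dtype=float)
    result.attrs["n_unannotated"] = n_unannotated
    return result
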