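"""Horizontal-gene-transfer screening by extended-best-hit taxonomic binning.

Each focal-genome protein carries a set of scored homology hits against a
taxonomically labelled database.  Hits within ``top_percent`` of the best
bitscore define the taxonomic bin; the query is assigned to the lowest common
ancestor of the retained hits' taxa.  Queries assigned at or below an order
other than the focal one are HGT candidates, subject to a filter cascade
(minimum best bitscore, transposable-element flags, split-alignment
artefacts) and finally to a gene-tree placement test: a candidate is
supported when its gene-tree leaf nests inside a clade made up purely of
donor-order sequences, away from the focal order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .taxonomy import Taxonomy


@dataclass
class BinningParams:
    """Extended-best-hit binning parameters (MEGAN-style LCA settings)."""

    top_percent: float = 40.0
    min_score: float = 50.0
    min_support: int = 1
    max_expected: float = 0.01
    lca_percent: float = 100.0
    min_percent_identity: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.top_percent <= 100:
            raise ValueError("top_percent must be in (0, 100]")


@dataclass
class HitRecord:
    """One scored homology hit of a focal query against a database sequence."""

    query: str
    subject: str
    subject_taxon: str
    bitscore: float
    evalue: float
    query_interval: tuple[int, int] = (0, 0)
    subject_interval: tuple[int, int] = (0, 0)
    pident: float = 100.0


@dataclass
class CandidateRecord:
    gene: str
    assigned_taxon: str
    donor_order: str
    best_bitscore: float
    donor_support: int = 0
    flags: list[str] = field(default_factory=list)
    supported_by_tree: str | None = None  # supported / not_supported / uninformative


def _prefilter(hits: Sequence[HitRecord], params: BinningParams) -> list[HitRecord]:
    return [
        h
        for h in hits
        if h.evalue <= params.max_expected
        and h.bitscore >= params.min_score
        and h.pident >= params.min_percent_identity
    ]


def retention_threshold(hits: Sequence[HitRecord], params: BinningParams) -> float | None:
    """Bitscore floor for bin membership: (1 - top_percent/100) x best hit."""
    kept = _prefilter(hits, params)
    if not kept:
        return None
    best = max(h.bitscore for h in kept)
    return (1.0 - params.top_percent / 100.0) * best


def retained_hits(hits: Sequence[HitRecord], params: BinningParams) -> list[HitRecord]:
    kept = _prefilter(hits, params)
    if not kept:
        return []
    thr = (1.0 - params.top_percent / 100.0) * max(h.bitscore for h in kept)
    return [h for h in kept if h.bitscore >= thr]


def weighted_lca_assign(
    hits: Sequence[HitRecord], taxonomy: Taxonomy, params: BinningParams | None = None
) -> str | None:
    """Assign one query to a taxonomy node from its retained hits.

    With ``lca_percent=100`` this is the strict LCA of all retained taxa.
    Lower values walk down from the root as long as a child's subtree still
    holds at least that percentage of the retained hits.  Returns None when
    no hit survives the pre-filters.
    """
    params = params or BinningParams()
    kept = retained_hits(hits, params)
    if len(kept) < params.min_support:
        return None
    taxa = [h.subject_taxon for h in kept]
    if params.lca_percent >= 100.0:
        return taxonomy.lca(taxa)
    # descend while some child of the current node covers enough of the hits
    total = len(taxa)
    node_counts: Counter[str] = Counter()
    for t in taxa:
        node_counts.update(taxonomy.ancestors(t))
    current = taxonomy.root
    while True:
        children = [
            n for n, nd in taxonomy.nodes.items()
            if nd.parent == current and node_counts.get(n, 0) > 0
        ]
        viable = [
            c for c in children
            if node_counts[c] * 100.0 >= params.lca_percent * total
        ]
        if not viable:
            return current
        current = max(viable, key=lambda c: (node_counts[c], c))


def split_alignment_flag(
    pair_hits: Sequence[HitRecord], threshold: float
) -> bool:
    """Detect a full-length alignment split in two by a short insertion.

    Flags the query/subject pair when >= 2 hits occupy non-overlapping query
    intervals, each scores below the retention ``threshold``, yet some
    disjoint combination of them would reach it.  Such pairs were dropped in
    the screen because the low individual bitscores are an alignment artefact
    rather than genuine divergence.
    """
    low = [h for h in pair_hits if h.bitscore < threshold]
    if len(low) < 2:
        return False
    # max-weight disjoint interval subset (tiny n: simple DP after sorting)
    low.sort(key=lambda h: h.query_interval[1])
    best_sum = [0.0] * (len(low) + 1)
    best_cnt = [0] * (len(low) + 1)
    for i, h in enumerate(low, start=1):
        s, e = h.query_interval
        j = i - 1
        while j > 0 and low[j - 1].query_interval[1] > s:
            j -= 1
        take_sum = best_sum[j] + h.bitscore
        take_cnt = best_cnt[j] + 1
        if take_sum > best_sum[i - 1]:
            best_sum[i], best_cnt[i] = take_sum, take_cnt
        else:
            best_sum[i], best_cnt[i] = best_sum[i - 1], best_cnt[i - 1]
    return best_cnt[-1] >= 2 and best_sum[-1] >= threshold


def donor_order(
    assigned_taxon: str,
    hits: Sequence[HitRecord],
    taxonomy: Taxonomy,
    params: BinningParams | None = None,
) -> tuple[str, int]:
    """(order ancestor of the assignment, number of retained hits inside it)."""
    params = params or BinningParams()
    order = taxonomy.order_of(assigned_taxon)
    if order is None:
        raise ValueError(f"assignment {assigned_taxon!r} is above order rank")
    support = sum(
        1 for h in retained_hits(hits, params)
        if taxonomy.order_of(h.subject_taxon) == order
    )
    return order, support


def screen_candidates(
    assignments: Mapping[str, str | None],
    hits_by_query: Mapping[str, Sequence[HitRecord]],
    taxonomy: Taxonomy,
    focal_order: str,
    params: BinningParams | None = None,
    te_flags: Iterable[str] = (),
    min_best_bitscore: float = 80.0,
) -> list[CandidateRecord]:
    """Filter binned queries down to high-confidence HGT candidates.

    A query is a candidate iff its assignment sits at or below an order rank
    different from ``focal_order``, its best bitscore strictly exceeds
    ``min_best_bitscore`` (scores of 80 or lower undermine the top-percent
    rule), it carries no transposable-element/retrovirus flag, and none of
    its subjects shows a split-alignment artefact.
    """
    params = params or BinningParams()
    te_set = set(te_flags)
    out: list[CandidateRecord] = []
    for gene in sorted(assignments):
        node = assignments[gene]
        if node is None:
            continue
        order = taxonomy.order_of(node)
        if order is None or order == focal_order:
            continue
        hits = list(hits_by_query.get(gene, ()))
        kept = _prefilter(hits, params)
        if not kept:
            continue
        best = max(h.bitscore for h in kept)
        flags: list[str] = []
        if best <= min_best_bitscore:
            flags.append("low_score")
        if gene in te_set:
            flags.append("te_like")
        thr = (1.0 - params.top_percent / 100.0) * best
        by_subject: dict[str, list[HitRecord]] = {}
        for h in kept:
            by_subject.setdefault(h.subject, []).append(h)
        if any(split_alignment_flag(hs, thr) for hs in by_subject.values()):
            flags.append("split_alignment")
        if flags:
            continue
        order_name, support = donor_order(node, hits, taxonomy, params)
        out.append(
            CandidateRecord(
                gene=gene,
                assigned_taxon=node,
                donor_order=order_name,
                best_bitscore=best,
                donor_support=support,
            )
        )
    return out


def load_curated_candidate_table() -> pd.DataFrame:
    """Curated HGT-candidate category table (synthetic stand-in ids).

    The categories and their sizes mirror the curated candidate set that
    enters gene-tree/species-tree reconciliation: previously reported albumin
    and strictosidine-synthase-like transfers plus the novel genome-wide
    candidates.  Gene ids are synthetic placeholders.
    """
    ref = resources.files("dodderprint").joinpath(
        "data/hgt_candidate_categories.synthetic.tsv"
    )
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def candidate_category_tally(table: pd.DataFrame) -> tuple[dict[str, int], int]:
    """Per-category counts and the total number of candidates entering the
    reconciliation stage."""
    if "category" not in table.columns:
        raise ValueError("candidate table needs a 'category' column")
    counts = table["category"].value_counts().to_dict()
    return {str(k): int(v) for k, v in counts.items()}, int(len(table))


def _as_tree(tree: "dendropy.Tree | str") -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(
        data=tree, schema="newick", preserve_underscores=True
    )


def placement_support(
    tree: "dendropy.Tree | str",
    leaf_orders: Mapping[str, str],
    focal_leaf: str,
    donor: str,
    focal_order: str,
) -> str:
    """Monophyly test of a candidate's gene-tree placement.

    ``supported``: the smallest clade containing the focal leaf plus at least
    one other leaf consists solely of donor-order leaves.  ``not_supported``:
    the focal leaf's sister group contains focal-order leaves (the placement
    expected without transfer).  Anything else is ``uninformative``, as is a
    tree without donor-order leaves.
    """
    tree = _as_tree(tree).clone(depth=1)
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if focal_leaf not in labels:
        raise ValueError(f"focal leaf {focal_leaf!r} missing from gene tree")

    def order_of_leaf(label: str) -> str | None:
        return leaf_orders.get(label)

    donor_leaves = [
        l for l in labels if l != focal_leaf and order_of_leaf(l) == donor
    ]
    if not donor_leaves:
        return "uninformative"

    # Root unrooted trees on the most distant leaf outside both the donor and
    # the focal order, so the focal leaf's neighbourhood is interpretable.
    seed_children = len(tree.seed_node.child_nodes())
    if not tree.is_rooted and seed_children > 2:
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        focal_taxon = taxa[focal_leaf]
        outgroup_pool = [
            l for l in labels
            if l != focal_leaf and order_of_leaf(l) not in (donor, focal_order)
        ]
        if outgroup_pool:
            out_label = max(
                outgroup_pool,
                key=lambda l: (pdm.patristic_distance(focal_taxon, taxa[l]), l),
            )
            out_node = tree.find_node_with_taxon_label(out_label)
            tree.to_outgroup_position(out_node, update_bipartitions=True)

    focal_node = tree.find_node_with_taxon_label(focal_leaf)
    node = focal_node.parent_node
    while node is not None:
        clade = {
            lf.taxon.label for lf in node.leaf_iter() if lf.taxon.label != focal_leaf
        }
        if clade:
            break
        node = node.parent_node
    if node is None or not clade:
        return "uninformative"

    clade_orders = {order_of_leaf(l) for l in clade}
    if clade_orders == {donor}:
        return "supported"
    if focal_order in clade_orders:
        return "not_supported"
    return "uninformative"
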