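"""A minimal ranked taxonomy for taxonomic binning of homology hits.

Only what LCA-style binning needs: named nodes with a rank, parent pointers,
ancestor paths, and order-level lookups.  Real analyses would load the NCBI
taxonomy; the synthetic screens here use a small plant taxonomy in which a
focal order (the parasite's) is distinguished from candidate donor orders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass
class TaxonNode:
    name: str
    parent: str | None
    rank: str


class Taxonomy:
    """Rooted tree of named, ranked taxa."""

    def __init__(self) -> None:
        self.nodes: dict[str, TaxonNode] = {}
        self.root: str | None = None

    def add(self, name: str, parent: str | None, rank: str) -> None:
        if name in self.nodes:
            raise ValueError(f"duplicate taxon name: {name}")
        if parent is None:
            if self.root is not None:
                raise ValueError("taxonomy already has a root")
            self.root = name
        elif parent not in self.nodes:
            raise ValueError(f"unknown parent taxon: {parent}")
        self.nodes[name] = TaxonNode(name, parent, rank)

    @classmethod
    def from_table(cls, rows: Iterable[tuple[str, str | None, str]]) -> "Taxonomy":
        """Build from (name, parent, rank) rows; the root row has parent None."""
        tax = cls()
        for name, parent, rank in rows:
            tax.add(name, parent if parent else None, rank)
        return tax

    def ancestors(self, name: str) -> list[str]:
        """Path from the node itself up to the root (inclusive)."""
        if name not in self.nodes:
            raise KeyError(f"unknown taxon: {name}")
        path = [name]
        while (parent := self.nodes[path[-1]].parent) is not None:
            path.append(parent)
        return path

    def lca(self, names: Sequence[str]) -> str:
        """Lowest common ancestor by ancestor-path intersection."""
        if not names:
            raise ValueError("lca of an empty taxon set")
        common = set(self.ancestors(names[0]))
        for name in names[1:]:
            common &= set(self.ancestors(name))
        # deepest member of the common set = first on any path
        for node in self.ancestors(names[0]):
            if node in common:
                return node
        raise RuntimeError("disconnected taxonomy")  # pragma: no cover

    def order_of(self, name: str) -> str | None:
        """The order-rank ancestor (or the node itself), None if above order."""
        for node in self.ancestors(name):
            if self.nodes[node].rank == "order":
                return node
        return None

    def orders(self) -> list[str]:
        return sorted(n for n, node in self.nodes.items() if node.rank == "order")

    def species_under(self, name: str) -> list[str]:
        """Species-rank descendants of a node (includes the node if a species)."""
        out = []
        for cand, node in self.nodes.items():
            if node.rank == "species" and name in self.ancestors(cand):
                out.append(cand)
        return sorted(out)


def make_toy_taxonomy() -> Taxonomy:
    """Small plant taxonomy: a focal order (Solanales, holding the parasite)
    plus plausible donor orders with a couple of species each."""
    rows = [
        ("Viridiplantae", None, "kingdom"),
        ("Solanales", "Viridiplantae", "order"),
        ("Fabales", "Viridiplantae", "order"),
        ("Caryophyllales", "Viridiplantae", "order"),
        ("Brassicales", "Viridiplantae", "order"),
        ("Apiales", "Viridiplantae", "order"),
        ("Convolvulaceae", "Solanales", "family"),
        ("Solanaceae", "Solanales", "family"),
        ("Fabaceae", "Fabales", "family"),
        ("Amaranthaceae", "Caryophyllales", "family"),
        ("Brassicaceae", "Brassicales", "family"),
        ("Apiaceae", "Apiales", "family"),
        ("dodder", "Convolvulaceae", "species"),
        ("morning_glory", "Convolvulaceae", "species"),
        ("tomato", "Solanaceae", "species"),
        ("soybean", "Fabaceae", "species"),
        ("medicago", "Fabaceae", "species"),
        ("amaranth", "Amaranthaceae", "species"),
        ("spinach", "Amaranthaceae", "species"),
        ("arabidopsis", "Brassicaceae", "species"),
        ("carrot", "Apiaceae", "species"),
    ]
    return Taxonomy.from_table(rows)


def toy_species_tree_newick() -> str:
    """Species tree over the toy taxonomy's species, rooted, with the focal
    lineage (dodder) nested inside Solanales as in the plant phylogeny."""
    return (
        "((((dodder:1,morning_glory:1):1,tomato:2):2,"
        "(((soybean:1,medicago:1):2,arabidopsis:3):1,"
        "(amaranth:1,spinach:1):3):1):1,carrot:5):1;"
    )
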