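"""Shared fixtures: toy taxonomy, species tree, and element builders."""

from __future__ import annotations

import pytest

from dodderprint.repeat_ltr import (
    DomainAnnotation,
    FullLengthElement,
    Interval,
    LTRCandidate,
)
from dodderprint.taxonomy import Taxonomy, make_toy_taxonomy, toy_species_tree_newick


@pytest.fixture(scope="session")
def toy_taxonomy() -> Taxonomy:
    return make_toy_taxonomy()


@pytest.fixture(scope="session")
def species_tree_newick() -> str:
    return toy_species_tree_newick()


@pytest.fixture(scope="session")
def leaf_orders(toy_taxonomy) -> dict[str, str]:
    return {
        sp: toy_taxonomy.order_of(sp)
        for sp in toy_taxonomy.species_under("Viridiplantae")
    }


def make_element(
    element_id: str = "el",
    domains: tuple[str, ...] = ("GAG", "RT", "RH", "INT"),
    strands: tuple[str, ...] | None = None,
    tandem_fraction: float = 0.10,
    n_fraction: float = 0.01,
    element_length: int = 5000,
    ltr_length: int = 500,
    sequence: str | None = None,
) -> FullLengthElement:
    """A structurally valid element, configurable to violate single criteria."""
    if strands is None:
        strands = ("+",) * len(domains)
    cand = LTRCandidate(
        element=Interval("genome", 0, element_length),
        ltr5=Interval("genome", 0, ltr_length),
        ltr3=Interval("genome", element_length - ltr_length, element_length),
        tsd_length=5,
        motif_ok=True,
        ltr_similarity=98.0,
    )
    anns = [
        DomainAnnotation(element_id, dom, i, strand)
        for i, (dom, strand) in enumerate(zip(domains, strands))
    ]
    return FullLengthElement(
        element_id=element_id,
        candidate=cand,
        domains=anns,
        tandem_fraction=tandem_fraction,
        n_fraction=n_fraction,
        sequence=sequence,
    )
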