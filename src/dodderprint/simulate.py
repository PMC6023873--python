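"""Synthetic genomes, reads, matrices, codon pairs, hit tables and gene trees
with recorded ground truth.

Every downstream stage of the package is exercised against data produced
here, so each generator plants a truth table alongside its output: LTR
element coordinates and ages, read provenance, orthogroup copy-number
classes, pairwise synonymous divergence, and HGT donor orders.  All
randomness flows from a single seeded NumPy generator per scenario; the same
``ScenarioConfig`` therefore reproduces byte-identical outputs.

Model choices (deliberately minimal):

* LTR elements are planted with two initially identical LTR copies.  Each
  copy is then mutated i.i.d. at per-site rate q = (3/4)(1 - sqrt(1 - (4/3) d))
  with d = 2 * mutation_rate * age, the Jukes-Cantor inverse that makes the
  *expected raw p-distance* between the copies exactly d, keeping the
  age = divergence / (2 mu) dating formula exact.  No indels.
* Reads are uniform-coverage with i.i.d. substitution errors only.
* Paralog pairs receive synonymous-only substitutions whose count is drawn
  to match the target expected NG86 dS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from ._codon import (
    SENSE_CODONS,
    synonymous_alternatives,
    synonymous_site_fraction,
)
from .hgt_screen import HitRecord
from .taxonomy import Taxonomy

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ScenarioConfig:
    """All tunables of a synthetic scenario; seed fixes every output."""

    seed: int = 0
    # genome / LTR planting
    genome_length: int = 1_000_000
    n_elements: int = 100
    planted_ages: Sequence[float] = (1_500_000.0,)
    mutation_rate: float = 7e-9
    ltr_length: int = 1000
    internal_length: int = 3000
    # read simulation
    read_length: int = 100
    coverage: float = 50.0
    error_rate: float = 0.01
    insert_size: int = 500
    # orthogroup matrix
    n_orthogroups: int = 1000
    loss_fraction: float = 0.1
    dup_fraction: float = 0.1
    n_species: int = 9
    # paralog pairs
    n_pairs: int = 500
    n_codons: int = 300
    true_ds: float = 0.05
    # HGT hit tables
    n_genes: int = 1000
    hgt_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in ("error_rate", "loss_fraction", "dup_fraction", "hgt_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.true_ds < 0:
            raise ValueError("true_ds must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class PlantedElement:
    """Ground truth for one planted LTR retrotransposon (0-based half-open)."""

    element_id: str
    start: int
    end: int
    ltr5_start: int
    ltr5_end: int
    ltr3_start: int
    ltr3_end: int
    tsd_length: int
    age_years: float
    expected_divergence: float


def _decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def _mutate(codes: np.ndarray, q: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability q, uniformly to another base."""
    out = codes.copy()
    mask = rng.random(codes.size) < q
    shifts = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
    out[mask] = (out[mask] + shifts) % 4
    return out


def _per_copy_rate(divergence: float) -> float:
    """Per-copy mutation rate whose independent application to both copies
    yields an expected pairwise p-distance of exactly ``divergence``."""
    if divergence >= 0.75:
        raise ValueError(
            f"planted divergence {divergence:.3f} saturates the p-distance; "
            "use a smaller age or mutation rate"
        )
    return 0.75 * (1.0 - math.sqrt(1.0 - (4.0 / 3.0) * divergence))


def simulate_genome_with_ltrs(
    config: ScenarioConfig,
) -> tuple[str, list[PlantedElement], pd.DataFrame]:
    """Random genome carrying full-length LTR elements of planted ages.

    Each element is TSD + LTR5 + internal + LTR3 + TSD; the LTRs start TG and
    end CA, the 4-20 bp target-site duplication is exact, and the two LTR
    copies diverge according to the planted age.  Returns the genome string,
    the planted-element records, and the same truth as a DataFrame.
    """
    rng = config.rng()
    n = config.n_elements
    ages = list(config.planted_ages)
    if n > 0 and not ages:
        raise ValueError("planted_ages must be non-empty when n_elements > 0")
    if n > 0:
        ages = [ages[i % len(ages)] for i in range(n)]

    cassettes: list[np.ndarray] = []
    meta: list[dict] = []
    for i in range(n):
        age = float(ages[i])
        div = 2.0 * config.mutation_rate * age
        q = _per_copy_rate(div)
        tsd_len = int(rng.integers(4, 21))
        ltr = _random_codes(rng, config.ltr_length)
        ltr[0:2] = [3, 2]            # TG
        ltr[-2:] = [1, 0]            # CA
        copy5 = _mutate(ltr, q, rng)
        copy3 = _mutate(ltr, q, rng)
        internal = _random_codes(rng, config.internal_length)
        tsd = _random_codes(rng, tsd_len)
        cassette = np.concatenate([tsd, copy5, internal, copy3, tsd])
        cassettes.append(cassette)
        meta.append({"age": age, "div": div, "tsd": tsd_len})

    total = sum(c.size for c in cassettes)
    slack = config.genome_length - total
    if slack < 0:
        raise ValueError(
            f"genome_length {config.genome_length} too small to place "
            f"{n} non-overlapping elements totalling {total} bp"
        )
    offsets = np.sort(rng.integers(0, slack + 1, size=n)) if n else np.empty(0, int)

    background = _random_codes(rng, slack)
    pieces: list[np.ndarray] = []
    elements: list[PlantedElement] = []
    cursor_bg = 0   # consumed background
    cursor_gen = 0  # position in the final genome
    for i in range(n):
        gap = int(offsets[i]) - cursor_bg
        pieces.append(background[cursor_bg:cursor_bg + gap])
        cursor_bg += gap
        cursor_gen += gap
        cassette = cassettes[i]
        tsd_len = meta[i]["tsd"]
        el_start = cursor_gen + tsd_len
        el_end = cursor_gen + cassette.size - tsd_len
        elements.append(
            PlantedElement(
                element_id=f"ltr_{i:05d}",
                start=el_start,
                end=el_end,
                ltr5_start=el_start,
                ltr5_end=el_start + config.ltr_length,
                ltr3_start=el_end - config.ltr_length,
                ltr3_end=el_end,
                tsd_length=tsd_len,
                age_years=meta[i]["age"],
                expected_divergence=meta[i]["div"],
            )
        )
        pieces.append(cassette)
        cursor_gen += cassette.size
    pieces.append(background[cursor_bg:])
    genome = _decode(np.concatenate(pieces) if pieces else np.empty(0, np.uint8))

    truth = pd.DataFrame([vars(e) for e in elements])
    return genome, elements, truth


def _reads_matrix(
    genome_codes: np.ndarray,
    starts: np.ndarray,
    length: int,
    strands: np.ndarray,
    error_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    mat = genome_codes[starts[:, None] + np.arange(length)[None, :]]
    rev = strands == 1
    mat[rev] = 3 - mat[rev][:, ::-1]  # reverse complement
    if error_rate > 0:
        mask = rng.random(mat.shape) < error_rate
        shifts = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        mat[mask] = (mat[mask] + shifts) % 4
    return mat


def simulate_reads(
    genome: str, config: ScenarioConfig, prefix: str = "read"
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Uniform-coverage single-end reads with i.i.d. substitution errors.

    The number of reads is coverage * genome_length / read_length (rounded).
    Truth records each read's start and strand.
    """
    if config.coverage <= 0:
        raise ValueError("coverage must be > 0")
    g = len(genome)
    length = config.read_length
    if length > g:
        raise ValueError("read_length exceeds genome length")
    rng = config.rng()
    n_reads = int(round(config.coverage * g / length))
    starts = rng.integers(0, g - length + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    codes = np.frombuffer(genome.encode("ascii"), dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.uint8)
    lut[b"A"[0]], lut[b"C"[0]], lut[b"G"[0]], lut[b"T"[0]] = 0, 1, 2, 3
    mat = _reads_matrix(lut[codes], starts, length, strands, config.error_rate, rng)
    ascii_mat = _DECODE[mat]
    reads = [
        (f"{prefix}_{i:07d}", ascii_mat[i].tobytes().decode("ascii"))
        for i in range(n_reads)
    ]
    truth = pd.DataFrame(
        {
            "read_id": [r[0] for r in reads],
            "start": starts,
            "strand": np.where(strands == 1, "-", "+"),
        }
    )
    return reads, truth


def simulate_read_pairs(
    genome: str, config: ScenarioConfig, prefix: str = "pair"
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Inward-facing read pairs from fragments of ``config.insert_size``."""
    g = len(genome)
    length = config.read_length
    insert = config.insert_size
    if insert > g or length > insert:
        raise ValueError("insert_size must satisfy read_length <= insert <= genome")
    rng = config.rng()
    n_pairs = int(round(config.coverage * g / (2 * length)))
    frag_starts = rng.integers(0, g - insert + 1, size=n_pairs)
    codes = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    lut[b"A"[0]], lut[b"C"[0]], lut[b"G"[0]], lut[b"T"[0]] = 0, 1, 2, 3
    gcodes = lut[codes]
    fwd = _reads_matrix(
        gcodes, frag_starts, length, np.zeros(n_pairs, int), config.error_rate, rng
    )
    rev = _reads_matrix(
        gcodes,
        frag_starts + insert - length,
        length,
        np.ones(n_pairs, int),
        config.error_rate,
        rng,
    )
    fa, ra = _DECODE[fwd], _DECODE[rev]
    pairs = [
        (
            f"{prefix}_{i:07d}",
            fa[i].tobytes().decode("ascii"),
            ra[i].tobytes().decode("ascii"),
        )
        for i in range(n_pairs)
    ]
    truth = pd.DataFrame(
        {"pair_id": [p[0] for p in pairs], "fragment_start": frag_starts}
    )
    return pairs, truth


def simulate_orthogroup_matrix(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Orthogroup x species count matrix with planted copy-number classes.

    ``loss_fraction`` of rows are strict losses (focal 0, every other species
    1), ``dup_fraction`` are exact duplications (focal 2, every other 1), and
    the remainder are universal single-copy rows.  The focal species is the
    first column, named ``focal``.
    """
    if config.n_species < 2:
        raise ValueError("need at least 2 species")
    if config.loss_fraction + config.dup_fraction > 1:
        raise ValueError("loss_fraction + dup_fraction must not exceed 1")
    rng = config.rng()
    n = config.n_orthogroups
    n_loss = int(round(config.loss_fraction * n))
    n_dup = int(round(config.dup_fraction * n))
    labels = (
        ["loss_strict"] * n_loss
        + ["dup_exact"] * n_dup
        + ["single_copy_universal"] * (n - n_loss - n_dup)
    )
    rng.shuffle(labels)
    species = ["focal"] + [f"species_{i}" for i in range(1, config.n_species)]
    focal_counts = {"loss_strict": 0, "dup_exact": 2, "single_copy_universal": 1}
    data = {
        "focal": [focal_counts[l] for l in labels],
        **{s: [1] * n for s in species[1:]},
    }
    index = [f"OG{i:07d}" for i in range(n)]
    matrix = pd.DataFrame(data, index=index)
    truth = pd.DataFrame({"orthogroup": index, "label": labels}).set_index("orthogroup")
    return matrix, truth


def _random_sense_codons(rng: np.random.Generator, n_codons: int) -> list[str]:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return [SENSE_CODONS[i] for i in idx]


def simulate_paralog_pairs(
    config: ScenarioConfig,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Codon-sequence pairs with planted synonymous-only divergence.

    The substitution count per pair is drawn so the expected NG86 dS equals
    ``config.true_ds``: target pS from the Jukes-Cantor forward map, times
    the sequence's NG86 synonymous site count, stochastically rounded.  Only
    amino-acid-preserving single-nucleotide changes are applied, so no stop
    codons can arise.
    """
    rng = config.rng()
    target_ps = 0.75 * (1.0 - math.exp(-(4.0 / 3.0) * config.true_ds))
    pairs: list[tuple[str, str, str]] = []
    rows = []
    for i in range(config.n_pairs):
        codons = _random_sense_codons(rng, config.n_codons)
        s_sites = sum(synonymous_site_fraction(c) for c in codons)
        mutable = [j for j, c in enumerate(codons) if synonymous_alternatives(c)]
        target = target_ps * s_sites
        n_sub = int(math.floor(target))
        if rng.random() < target - n_sub:
            n_sub += 1
        if n_sub > len(mutable):
            raise ValueError(
                "true_ds too large for these sequences; choose a smaller value"
            )
        chosen = rng.choice(len(mutable), size=n_sub, replace=False) if n_sub else []
        derived = list(codons)
        for j in chosen:
            pos = mutable[int(j)]
            alts = synonymous_alternatives(derived[pos])
            derived[pos] = alts[int(rng.integers(0, len(alts)))]
        pair_id = f"pair_{i:05d}"
        pairs.append((pair_id, "".join(codons), "".join(derived)))
        rows.append({"pair_id": pair_id, "true_ds": config.true_ds, "n_sub": n_sub})
    truth = pd.DataFrame(rows).set_index("pair_id")
    return pairs, truth


def simulate_hit_table(
    taxonomy: Taxonomy,
    config: ScenarioConfig,
    focal_order: str = "Solanales",
    donor_orders: Sequence[str] | None = None,
    top_percent: float = 40.0,
) -> tuple[list[HitRecord], pd.DataFrame]:
    """BLAST-like hit table over a ranked taxonomy with planted HGT genes.

    Non-HGT genes get their retained (top-percent band) hits exclusively in
    the focal lineage, with out-of-order hits scored safely below the
    retention threshold.  Planted HGT genes get high donor-order hits
    (bitscore >= 100) and focal-lineage hits below the threshold.
    """
    if donor_orders is None:
        donor_orders = [o for o in taxonomy.orders() if o != focal_order]
    n_hgt = int(round(config.hgt_fraction * config.n_genes))
    if n_hgt > 0 and not donor_orders:
        raise ValueError("hgt_fraction > 0 requires at least one donor order")
    focal_species = taxonomy.species_under(focal_order)
    if not focal_species:
        raise ValueError(f"no species under focal order {focal_order!r}")
    donor_species = {o: taxonomy.species_under(o) for o in donor_orders}
    rng = config.rng()
    hgt_idx = set(
        rng.choice(config.n_genes, size=n_hgt, replace=False).tolist()
    ) if n_hgt else set()

    keep_frac = 1.0 - top_percent / 100.0  # retention threshold = frac * best
    hits: list[HitRecord] = []
    rows = []
    for i in range(config.n_genes):
        gene = f"gene_{i:05d}"
        if i in hgt_idx:
            donor = donor_orders[int(rng.integers(0, len(donor_orders)))]
            best = float(rng.uniform(150.0, 300.0))
            pool = donor_species[donor]
            n_top = int(rng.integers(2, 5))
            for j in range(n_top):
                sp = pool[int(rng.integers(0, len(pool)))]
                score = best if j == 0 else float(
                    rng.uniform(max(100.0, (keep_frac + 0.05) * best), best)
                )
                hits.append(_hit(gene, f"{sp}_prot{j}", sp, score))
            # focal-lineage hits stay below the retention threshold
            for j in range(2):
                sp = focal_species[int(rng.integers(0, len(focal_species)))]
                score = float(rng.uniform(50.0, (keep_frac - 0.1) * best))
                hits.append(_hit(gene, f"{sp}_prot{j}", sp, score))
            rows.append({"gene": gene, "is_hgt": True, "donor_order": donor})
        else:
            best = float(rng.uniform(150.0, 400.0))
            n_top = int(rng.integers(2, 5))
            for j in range(n_top):
                sp = focal_species[int(rng.integers(0, len(focal_species)))]
                score = best if j == 0 else float(
                    rng.uniform((keep_frac + 0.05) * best, best)
                )
                hits.append(_hit(gene, f"{sp}_prot{j}", sp, score))
            if donor_orders:
                donor = donor_orders[int(rng.integers(0, len(donor_orders)))]
                pool = donor_species[donor]
                sp = pool[int(rng.integers(0, len(pool)))]
                score = float(rng.uniform(50.0, (keep_frac - 0.1) * best))
                hits.append(_hit(gene, f"{sp}_protX", sp, score))
            rows.append({"gene": gene, "is_hgt": False, "donor_order": None})
    truth = pd.DataFrame(rows).set_index("gene")
    return hits, truth


def _hit(gene: str, subject: str, taxon: str, score: float) -> HitRecord:
    return HitRecord(
        query=gene,
        subject=subject,
        subject_taxon=taxon,
        bitscore=round(score, 1),
        evalue=1e-50,
        query_interval=(0, 200),
        subject_interval=(0, 200),
    )


def simulate_gene_trees(
    species_tree: "dendropy.Tree | str",
    truth: pd.DataFrame,
    taxonomy: Taxonomy,
    focal_species: str = "dodder",
) -> dict[str, dendropy.Tree]:
    """One gene tree per truth row, consistent with the planted HGT status.

    For a planted HGT gene the focal gene leaf is grafted as sister to a
    donor-order species leaf (so its smallest enclosing multi-leaf clade is
    purely donor-order); otherwise it is grafted sister to the focal species.
    Leaf set = species set + the focal gene leaf.
    """
    if isinstance(species_tree, str):
        base = dendropy.Tree.get(
            data=species_tree, schema="newick", preserve_underscores=True
        )
    else:
        base = species_tree
    species = sorted(lf.taxon.label for lf in base.leaf_node_iter())
    trees: dict[str, dendropy.Tree] = {}
    for gene, row in truth.iterrows():
        if row["is_hgt"]:
            donor = row["donor_order"]
            donor_sp = [s for s in species if taxonomy.order_of(s) == donor]
            if not donor_sp:
                raise ValueError(
                    f"donor order {donor!r} has no species in the species tree"
                )
            sister = donor_sp[0]
        else:
            sister = focal_species
        tree = base.clone(depth=1)
        tree.is_rooted = True
        leaf = tree.find_node_with_taxon_label(sister)
        parent = leaf.parent_node
        edge_len = leaf.edge.length or 1.0
        parent.remove_child(leaf)
        joint = parent.new_child(edge_length=edge_len / 2)
        leaf.edge.length = edge_len / 2
        joint.add_child(leaf)
        gene_taxon = tree.taxon_namespace.new_taxon(label=str(gene))
        joint.new_child(taxon=gene_taxon, edge_length=edge_len / 2)
        trees[str(gene)] = tree
    return trees
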