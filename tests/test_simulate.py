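"""Determinism, planted-truth recovery, and calibration of the generators."""

from __future__ import annotations

import numpy as np
import pytest

from dodderprint.ds_wgd import estimate_ds
from dodderprint.io import write_fastq
from dodderprint.ortho_dynamics import classify_orthogroups
from dodderprint.simulate import (
    ScenarioConfig,
    simulate_gene_trees,
    simulate_genome_with_ltrs,
    simulate_hit_table,
    simulate_orthogroup_matrix,
    simulate_paralog_pairs,
    simulate_reads,
)
from dodderprint._codon import STOP_CODONS


class TestGenomeWithLtrs:
    def test_no_elements_gives_plain_genome(self):
        cfg = ScenarioConfig(seed=1, genome_length=10_000, n_elements=0)
        genome, elements, truth = simulate_genome_with_ltrs(cfg)
        assert len(genome) == 10_000
        assert elements == [] and truth.empty

    def test_zero_age_gives_identical_ltr_copies(self):
        cfg = ScenarioConfig(
            seed=2, genome_length=60_000, n_elements=5, planted_ages=[0.0],
            ltr_length=400, internal_length=3000,
        )
        genome, elements, _ = simulate_genome_with_ltrs(cfg)
        for e in elements:
            assert genome[e.ltr5_start:e.ltr5_end] == genome[e.ltr3_start:e.ltr3_end]

    def test_structural_invariants_of_planted_elements(self):
        cfg = ScenarioConfig(
            seed=3, genome_length=120_000, n_elements=10, planted_ages=[1e6],
            ltr_length=300, internal_length=3000,
        )
        genome, elements, _ = simulate_genome_with_ltrs(cfg)
        prev_end = 0
        for e in sorted(elements, key=lambda x: x.start):
            assert e.start >= prev_end  # non-overlapping
            prev_end = e.end
            assert genome[e.start:e.start + 2] == "TG"
            assert genome[e.end - 2:e.end] == "CA"
            assert 4 <= e.tsd_length <= 20
            assert (
                genome[e.start - e.tsd_length:e.start]
                == genome[e.end:e.end + e.tsd_length]
            )

    def test_same_seed_reproduces_identical_fasta_bytes(self):
        cfg = ScenarioConfig(seed=7, genome_length=80_000, n_elements=5,
                             planted_ages=[1e6], ltr_length=300)
        g1, _, t1 = simulate_genome_with_ltrs(cfg)
        g2, _, t2 = simulate_genome_with_ltrs(cfg)
        assert g1.encode() == g2.encode()
        assert t1.equals(t2)

    def test_overfull_genome_errors_naming_constraint(self):
        cfg = ScenarioConfig(seed=4, genome_length=5_000, n_elements=10,
                             planted_ages=[0.0])
        with pytest.raises(ValueError, match="non-overlapping"):
            simulate_genome_with_ltrs(cfg)

    def test_planted_divergence_calibration(self):
        # mean pairwise LTR divergence within 3 SE of 2*mu*age (>=100 elements)
        age = 1.5e6
        cfg = ScenarioConfig(
            seed=11, genome_length=1_500_000, n_elements=150,
            planted_ages=[age], ltr_length=1000, internal_length=3000,
        )
        genome, elements, _ = simulate_genome_with_ltrs(cfg)
        divs = np.array([
            sum(
                a != b
                for a, b in zip(
                    genome[e.ltr5_start:e.ltr5_end], genome[e.ltr3_start:e.ltr3_end]
                )
            ) / (e.ltr5_end - e.ltr5_start)
            for e in elements
        ])
        expected = 2 * cfg.mutation_rate * age
        se = divs.std(ddof=1) / np.sqrt(len(divs))
        assert abs(divs.mean() - expected) <= 3 * se


class TestReads:
    def test_expected_read_count(self):
        cfg = ScenarioConfig(seed=1, genome_length=100_000, n_elements=0,
                             coverage=50, read_length=100)
        genome, _, _ = simulate_genome_with_ltrs(cfg)
        reads, truth = simulate_reads(genome, cfg)
        assert len(reads) == 50_000
        assert len(truth) == len(reads)

    def test_error_free_reads_are_genome_substrings(self):
        comp = str.maketrans("ACGT", "TGCA")
        cfg = ScenarioConfig(seed=5, genome_length=5_000, n_elements=0,
                             coverage=2, error_rate=0.0)
        genome, _, _ = simulate_genome_with_ltrs(cfg)
        reads, _ = simulate_reads(genome, cfg)
        for _, seq in reads[:200]:
            assert seq in genome or seq.translate(comp)[::-1] in genome

    def test_same_seed_identical_fastq(self, tmp_path):
        cfg = ScenarioConfig(seed=6, genome_length=5_000, n_elements=0, coverage=3)
        genome, _, _ = simulate_genome_with_ltrs(cfg)
        paths = []
        for tag in ("a", "b"):
            reads, _ = simulate_reads(genome, cfg)
            p = tmp_path / f"{tag}.fastq"
            write_fastq(reads, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_read_longer_than_genome_rejected(self):
        cfg = ScenarioConfig(seed=1, read_length=200)
        with pytest.raises(ValueError):
            simulate_reads("ACGT" * 10, cfg)


class TestOrthogroupMatrix:
    def test_planted_counts_match_config(self):
        cfg = ScenarioConfig(seed=2, n_orthogroups=100, loss_fraction=0.1,
                             dup_fraction=0.2)
        _, truth = simulate_orthogroup_matrix(cfg)
        counts = truth["label"].value_counts()
        assert counts["loss_strict"] == 10
        assert counts["dup_exact"] == 20

    def test_no_losses_when_fraction_zero(self):
        cfg = ScenarioConfig(seed=3, n_orthogroups=50, loss_fraction=0.0,
                             dup_fraction=0.1)
        matrix, _ = simulate_orthogroup_matrix(cfg)
        focal_zero = matrix[matrix["focal"] == 0]
        assert focal_zero.empty

    def test_classifier_round_trip_recovers_truth(self):
        cfg = ScenarioConfig(seed=4, n_orthogroups=300, loss_fraction=0.15,
                             dup_fraction=0.25)
        matrix, truth = simulate_orthogroup_matrix(cfg)
        labels = classify_orthogroups(matrix, focal="focal")
        assert (labels == truth["label"]).all()

    def test_fraction_sum_validated(self):
        with pytest.raises(ValueError):
            simulate_orthogroup_matrix(
                ScenarioConfig(seed=1, loss_fraction=0.6, dup_fraction=0.6)
            )


class TestParalogPairs:
    def test_zero_divergence_gives_identical_pairs(self):
        cfg = ScenarioConfig(seed=5, n_pairs=5, n_codons=50, true_ds=0.0)
        pairs, _ = simulate_paralog_pairs(cfg)
        assert all(a == b for _, a, b in pairs)

    def test_no_stop_codons_introduced(self):
        cfg = ScenarioConfig(seed=6, n_pairs=20, n_codons=100, true_ds=0.5)
        pairs, _ = simulate_paralog_pairs(cfg)
        for _, a, b in pairs:
            for seq in (a, b):
                codons = {seq[i:i + 3] for i in range(0, len(seq), 3)}
                assert not (codons & STOP_CODONS)

    def test_estimator_recovers_planted_ds(self):
        cfg = ScenarioConfig(seed=7, n_pairs=200, n_codons=300, true_ds=0.05)
        pairs, _ = simulate_paralog_pairs(cfg)
        ests = [estimate_ds((a, b)).ds for _, a, b in pairs]
        assert np.mean(ests) == pytest.approx(0.05, rel=0.10)

    def test_same_seed_identical_pairs(self):
        cfg = ScenarioConfig(seed=8, n_pairs=10, n_codons=60, true_ds=0.1)
        assert simulate_paralog_pairs(cfg)[0] == simulate_paralog_pairs(cfg)[0]


class TestHitTable:
    def test_planted_hgt_count(self, toy_taxonomy):
        cfg = ScenarioConfig(seed=9, n_genes=1000, hgt_fraction=0.05)
        _, truth = simulate_hit_table(toy_taxonomy, cfg)
        assert int(truth["is_hgt"].sum()) == 50

    def test_hgt_without_donor_orders_errors(self, toy_taxonomy):
        cfg = ScenarioConfig(seed=9, n_genes=10, hgt_fraction=0.5)
        with pytest.raises(ValueError, match="donor"):
            simulate_hit_table(toy_taxonomy, cfg, donor_orders=[])

    def test_planted_candidates_have_high_bitscores(self, toy_taxonomy):
        cfg = ScenarioConfig(seed=10, n_genes=200, hgt_fraction=0.1)
        hits, truth = simulate_hit_table(toy_taxonomy, cfg)
        hgt_genes = set(truth.index[truth["is_hgt"]])
        for g in hgt_genes:
            best = max(h.bitscore for h in hits if h.query == g)
            assert best >= 100


class TestGeneTrees:
    def test_leaf_set_is_species_plus_gene(self, toy_taxonomy, species_tree_newick):
        cfg = ScenarioConfig(seed=11, n_genes=20, hgt_fraction=0.2)
        _, truth = simulate_hit_table(toy_taxonomy, cfg)
        trees = simulate_gene_trees(species_tree_newick, truth.head(5), toy_taxonomy)
        species = set(toy_taxonomy.species_under("Viridiplantae"))
        for gene, tree in trees.items():
            leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
            assert leaves == species | {gene}

    def test_hgt_gene_nests_inside_donor_clade(self, toy_taxonomy, species_tree_newick):
        cfg = ScenarioConfig(seed=12, n_genes=50, hgt_fraction=0.3)
        _, truth = simulate_hit_table(toy_taxonomy, cfg)
        hgt = truth[truth["is_hgt"]].head(5)
        trees = simulate_gene_trees(species_tree_newick, hgt, toy_taxonomy)
        for gene, row in hgt.iterrows():
            tree = trees[gene]
            node = tree.find_node_with_taxon_label(gene).parent_node
            clade = {
                lf.taxon.label for lf in node.leaf_iter()
                if lf.taxon.label != gene
            }
            assert clade
            assert all(
                toy_taxonomy.order_of(l) == row["donor_order"] for l in clade
            )
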