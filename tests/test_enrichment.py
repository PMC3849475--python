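"""Tests for ATC, gene-term, pathway and candidate-overlap enrichment."""

from __future__ import annotations

import numpy as np
import pytest

from illicitnet import (
    CategoryMembership,
    atc_memberships,
    atc_second_level,
    candidate_overlap_test,
    drug_category_table,
    drugs_with_atc,
    enrich_drug_categories,
    enrich_gene_terms_comparative,
    enrich_pathways_within_set,
    fisher_exact_two_sided,
    load_membership_table,
)

from .conftest import make_drug
from .oracles import hypergeom_sf_exact


def sets_with_category(n_a, in_a, n_b, in_b, cat_id="N05"):
    """Two entity-id sets and a membership realizing given counts."""
    set_a = {f"A{i}" for i in range(n_a)}
    set_b = {f"B{i}" for i in range(n_b)}
    members = {f"A{i}" for i in range(in_a)} | {f"B{i}" for i in range(in_b)}
    return set_a, set_b, CategoryMembership(cat_id, cat_id, frozenset(members))


class TestAtcSecondLevel:
    @pytest.mark.parametrize(
        "code,expected", [("N05BA01", "N05"), ("A08AA10", "A08"), ("G03BA03", "G03")]
    )
    def test_prefix_slice(self, code, expected):
        assert atc_second_level(code) == expected

    @pytest.mark.parametrize("bad", ["X9", "N05BA0", "n05ba01", "N05BA011"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            atc_second_level(bad)

    def test_memberships_count_each_drug_once_per_category(self):
        records = [
            make_drug("DB1", atc_codes=("N05BA01", "N05CD02")),  # two codes, one category
            make_drug("DB2", atc_codes=("N05CD07", "A08AA10")),
            make_drug("DB3"),
        ]
        cats = {m.category_id: m.members for m in atc_memberships(records)}
        assert cats == {"N05": {"DB1", "DB2"}, "A08": {"DB2"}}
        assert drugs_with_atc(records) == {"DB1", "DB2"}


class TestDrugCategoryTable:
    def test_published_psycholeptics_counts(self):
        set_a, set_b, cat = sets_with_category(50, 24, 594, 3)
        table = drug_category_table(set_a, set_b, cat)
        assert (table.n_in_a, table.n_in_b, table.n_out_a, table.n_out_b) == (24, 3, 26, 591)
        assert fisher_exact_two_sided(table) == pytest.approx(1.2e-26, rel=0.05)

    def test_empty_category_gives_unit_p(self):
        set_a, set_b, cat = sets_with_category(5, 0, 7, 0)
        table = drug_category_table(set_a, set_b, cat)
        assert (table.n_in_a, table.n_in_b) == (0, 0)
        with pytest.warns(UserWarning):
            assert fisher_exact_two_sided(table) == 1.0

    def test_counts_match_brute_force_intersection(self):
        rng = np.random.default_rng(31)
        universe = [f"D{i}" for i in range(60)]
        set_a = set(rng.choice(universe, 20, replace=False))
        set_b = set(universe) - set_a
        members = frozenset(rng.choice(universe, 25, replace=False))
        table = drug_category_table(set_a, set_b, CategoryMembership("C", "C", members))
        assert table.n_in_a == len(set_a & members)
        assert table.n_in_b == len(set_b & members)
        assert table.size_a == len(set_a) and table.size_b == len(set_b)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            drug_category_table(set(), {"B1"}, CategoryMembership("C", "C", frozenset()))


class TestComparativeEnrichment:
    def test_published_category_is_significant(self):
        set_a, set_b, cat = sets_with_category(50, 24, 594, 3)
        results = enrich_drug_categories(set_a, set_b, [cat])
        assert results[0].significant
        assert results[0].count_a == 24
        assert results[0].pct_a == pytest.approx(48.0)

    def test_antisymmetry_swaps_columns_keeps_p(self):
        set_a, set_b, cat = sets_with_category(30, 10, 40, 5)
        fwd = enrich_drug_categories(set_a, set_b, [cat])[0]
        rev = enrich_drug_categories(set_b, set_a, [cat])[0]
        assert fwd.p == pytest.approx(rev.p, rel=1e-12)
        assert (fwd.count_a, fwd.count_b) == (rev.count_b, rev.count_a)

    def test_counts_reconstruct_set_sizes(self):
        set_a, set_b, cat = sets_with_category(30, 10, 40, 5)
        r = enrich_drug_categories(set_a, set_b, [cat])[0]
        table = drug_category_table(set_a, set_b, cat)
        assert r.count_a + table.n_out_a == len(set_a)
        assert r.count_b + table.n_out_b == len(set_b)

    def test_exclusive_category_matches_direct_fisher(self):
        set_a, set_b, cat = sets_with_category(8, 8, 12, 0)
        r = enrich_drug_categories(set_a, set_b, [cat])[0]
        from illicitnet.stats import ContingencyTable2x2

        assert r.p == pytest.approx(
            float(fisher_exact_two_sided(ContingencyTable2x2(8, 0, 0, 12))), rel=1e-12
        )

    def test_gene_terms_reproduce_published_ion_binding(self):
        genes_a, genes_b, cat = sets_with_category(73, 35, 1235, 432, cat_id="GO:0043167")
        r = enrich_gene_terms_comparative(genes_a, genes_b, [cat])[0]
        assert r.p == pytest.approx(0.032, rel=0.05)
        assert r.significant

    def test_term_covering_everything_is_null(self):
        genes_a, genes_b, cat = sets_with_category(10, 10, 20, 20)
        r = enrich_gene_terms_comparative(genes_a, genes_b, [cat])[0]
        assert r.p == 1.0

    def test_null_false_positive_rate_near_alpha(self):
        """No planted association: ~5% of categories reach p < 0.05."""
        rng = np.random.default_rng(0)
        hits = reps = 0
        from illicitnet.stats import ContingencyTable2x2

        for _ in range(500):
            a = int(rng.binomial(200, 0.3))
            b = int(rng.binomial(200, 0.3))
            p = fisher_exact_two_sided(ContingencyTable2x2(a, b, 200 - a, 200 - b))
            hits += p < 0.05
            reps += 1
        assert 0.02 <= hits / reps <= 0.08


class TestPathwaysWithinSet:
    def test_exact_pathway_match_ranks_first(self):
        genes = {f"G{i}" for i in range(10)}
        universe = {f"G{i}" for i in range(100)}
        pathways = [
            CategoryMembership("path_hit", "hit", frozenset(genes)),
            CategoryMembership("path_bg", "bg", frozenset({f"G{i}" for i in range(40, 70)})),
        ]
        results = enrich_pathways_within_set(genes, pathways, universe)
        assert results[0].category_id == "path_hit"
        assert results[0].p_adj == min(r.p_adj for r in results)
        assert results[0].significant

    def test_null_overlap_not_significant(self):
        # overlap at expectation: 10/100 universe in pathway, 3 of 30 drawn
        genes = {f"G{i}" for i in range(27, 57)}
        universe = {f"G{i}" for i in range(100)}
        pathway = CategoryMembership("p", "p", frozenset({f"G{i}" for i in range(20, 30)}))
        r = enrich_pathways_within_set(genes, [pathway], universe)[0]
        expected = float(hypergeom_sf_exact(100, 10, 30, 3))
        assert r.p == pytest.approx(expected, rel=1e-9)
        assert not r.significant

    def test_gene_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            enrich_pathways_within_set({"X"}, [], {"Y"})

    def test_adjustment_dominates_raw_p(self):
        genes = {f"G{i}" for i in range(5)}
        universe = {f"G{i}" for i in range(50)}
        pathways = [
            CategoryMembership(f"p{j}", f"p{j}", frozenset({f"G{(i + j) % 50}" for i in range(8)}))
            for j in range(6)
        ]
        for r in enrich_pathways_within_set(genes, pathways, universe):
            assert r.p_adj >= r.p - 1e-12


class TestCandidateOverlap:
    def test_published_scale_overlap(self):
        universe = {f"G{i}" for i in range(1333)}
        network = {f"G{i}" for i in range(73)}
        candidates = {f"G{i}" for i in range(17)} | {f"G{i}" for i in range(100, 130)}
        res = candidate_overlap_test(candidates, network, universe)
        assert (res.population, res.successes, res.draws, res.observed) == (1333, 47, 73, 17)
        assert float(res.p) == pytest.approx(4.17e-11, rel=0.05)
        assert float(res.p_point) == pytest.approx(3.9e-11, rel=0.05)

    def test_zero_overlap_gives_unit_p(self):
        universe = {f"G{i}" for i in range(50)}
        res = candidate_overlap_test(
            {f"G{i}" for i in range(40, 45)}, {f"G{i}" for i in range(10)}, universe
        )
        assert res.observed == 0
        assert float(res.p) == 1.0

    def test_small_fixture_matches_enumeration(self):
        universe = {f"G{i}" for i in range(10)}
        network = {f"G{i}" for i in range(5)}
        candidates = {"G0", "G1", "G2", "G9"}
        res = candidate_overlap_test(candidates, network, universe)
        assert float(res.p) == pytest.approx(float(hypergeom_sf_exact(10, 4, 5, 3)), rel=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            candidate_overlap_test({"A"}, set(), set())


def test_load_membership_table_long_format(tmp_path):
    body = (
        "category_id\tlabel\tmember_id\n"
        "N05\tPsycholeptics\tDB1\n"
        "N05\tPsycholeptics\tDB2\n"
        "A08\tAntiobesity\tDB1\n"
    )
    path = tmp_path / "members.tsv"
    path.write_text(body)
    cats = {m.category_id: m for m in load_membership_table(path)}
    assert cats["N05"].members == {"DB1", "DB2"}
    assert cats["A08"].label == "Antiobesity"
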