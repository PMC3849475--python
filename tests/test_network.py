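"""Tests for network construction, recruitment and partitioning."""

from __future__ import annotations

import numpy as np
import pytest

from illicitnet import (
    BipartiteNetwork,
    GeneTarget,
    annotate_set_labels,
    build_extended,
    build_network,
    find_illicit_related,
    mapping_report,
    partition_drugs,
    select_illicit,
)

from .conftest import make_drug


class TestSelectIllicit:
    def test_mixed_status_drug_selected(self):
        rec = make_drug("DB1", groups=("approved", "illicit"))
        assert select_illicit([rec]) == {"DB1"}

    def test_approved_only_not_selected(self):
        assert select_illicit([make_drug("DB1", groups=("approved",))]) == frozenset()

    def test_fixture_count(self, five_drug_records):
        assert select_illicit(five_drug_records) == {"DB00001", "DB00002"}


class TestBuildNetwork:
    def test_two_accessions_one_symbol_collapse_to_one_edge(self):
        mapping = {
            "P1": GeneTarget("P1", "GABRA1", 2554),
            "P2": GeneTarget("P2", "GABRA1", 2554),
        }
        net = build_network([make_drug("DB1", targets=("P1", "P2"))], mapping)
        assert net.edges == {("DB1", "GABRA1")}

    def test_drug_without_mappable_targets_excluded(self, small_mapping):
        records = [make_drug("DB1", targets=("P11111",)), make_drug("DB2", targets=("UNKNOWN",))]
        net = build_network(records, small_mapping)
        assert net.drug_nodes == {"DB1"}
        report = mapping_report(records, small_mapping)
        assert report.unmapped_accessions == {"UNKNOWN": 1}
        assert report.drugs_without_mapped_targets == {"DB2"}

    def test_non_human_targets_filtered(self, three_drug_xml, small_mapping):
        from illicitnet import parse_drugbank

        records = parse_drugbank(three_drug_xml)
        net = build_network(records, small_mapping)
        # DB00002's rat target P33333 must not produce an edge
        assert ("DB00002", "SLC6A3") not in net.edges
        assert ("DB00002", "OPRM1") in net.edges

    def test_edge_count_matches_planted_pairs(self):
        rng = np.random.default_rng(5)
        pairs = set()
        while len(pairs) < 17:
            pairs.add((f"DB{rng.integers(10):02d}", f"G{rng.integers(8)}"))
        by_drug: dict[str, list[str]] = {}
        for d, g in pairs:
            by_drug.setdefault(d, []).append(g)
        mapping = {f"ACC_{g}": GeneTarget(f"ACC_{g}", g, i) for i, g in enumerate({g for _, g in pairs})}
        records = [
            make_drug(d, targets=tuple(f"ACC_{g}" for g in genes)) for d, genes in by_drug.items()
        ]
        net = build_network(records, mapping)
        assert net.n_edges == 17
        assert net.edges == frozenset(pairs)

    def test_empty_result_warns_but_is_valid(self, small_mapping, caplog):
        with caplog.at_level("WARNING"):
            net = build_network([make_drug("DB1", targets=())], small_mapping)
        assert net.n_edges == 0 and net.n_nodes == 0

    def test_degree_sum_identity(self, five_drug_records, small_mapping):
        net = build_network(five_drug_records, small_mapping)
        from illicitnet.topology import degree

        deg = degree(net)
        assert sum(deg[d] for d in net.drug_nodes) == net.n_edges
        assert sum(deg[g] for g in net.gene_nodes) == net.n_edges


class TestIllicitRelated:
    def test_sharing_drug_included_illicit_excluded(self, five_drug_records, small_mapping):
        illicit = select_illicit(five_drug_records)
        related = find_illicit_related(five_drug_records, small_mapping, illicit)
        assert related == {"DB00003"}  # shares OPRM1; DB00004 targets ESR1 only

    def test_counted_overlap_fixture(self, small_mapping):
        records = [make_drug("DB_ILL", groups=("illicit",), targets=("P11111", "P22222"))]
        # 3 of 7 non-illicit drugs overlap the illicit targets
        for i, accs in enumerate(
            [("P11111",), ("P22222",), ("P11111", "P44444"), ("P44444",), ("P55555",), ("P44444", "P55555"), ()]
        ):
            records.append(make_drug(f"DB{i:03d}", targets=accs))
        related = find_illicit_related(records, small_mapping, {"DB_ILL"})
        assert related == {"DB000", "DB001", "DB002"}


class TestBuildExtended:
    def test_related_edges_restricted_to_illicit_targets(self, small_mapping):
        records = [
            make_drug("DB_ILL", groups=("illicit",), targets=("P11111", "P22222")),
            make_drug("DB_REL", targets=("P22222", "P44444", "P55555")),
        ]
        ext = build_extended(records, small_mapping, {"DB_ILL"})
        assert ("DB_REL", "OPRM1") in ext.edges
        assert all(g in {"GABRA1", "OPRM1"} for _, g in ext.edges)
        # one related target in the illicit set -> exactly one related edge
        assert sum(d == "DB_REL" for d, _ in ext.edges) == 1

    def test_node_count_identity_and_subgraph(self, five_drug_records, small_mapping):
        illicit = select_illicit(five_drug_records)
        ill_net = build_network(five_drug_records, small_mapping, illicit)
        ext = build_extended(five_drug_records, small_mapping, illicit)
        related = find_illicit_related(five_drug_records, small_mapping, illicit)
        assert ext.n_nodes == len(illicit) + len(related) + len(ill_net.gene_nodes)
        assert ill_net.is_subgraph_of(ext)
        assert ext.gene_nodes == ill_net.gene_nodes

    def test_edge_count_matches_brute_force_recount(self, small_mapping):
        rng = np.random.default_rng(17)
        accs = list(small_mapping)
        records = []
        for i in range(12):
            k = int(rng.integers(0, len(accs) + 1))
            targets = tuple(rng.choice(accs, size=k, replace=False))
            groups = ("illicit",) if rng.random() < 0.3 else ("approved",)
            records.append(make_drug(f"DB{i:03d}", groups=groups, targets=targets))
        illicit = select_illicit(records)
        ext = build_extended(records, small_mapping, illicit)
        # independent recount straight from the record list
        sym = {a: small_mapping[a].gene_symbol for a in small_mapping}
        genes_of = {
            r.drug_id: {sym[t.uniprot_acc] for t in r.target_refs if t.uniprot_acc in sym}
            for r in records
        }
        illicit_genes = set().union(*(genes_of[d] for d in illicit)) if illicit else set()
        expected = set()
        for r in records:
            if r.drug_id in illicit:
                expected |= {(r.drug_id, g) for g in genes_of[r.drug_id]}
            elif genes_of[r.drug_id] & illicit_genes:
                expected |= {(r.drug_id, g) for g in genes_of[r.drug_id] & illicit_genes}
        assert ext.edges == expected


class TestPartition:
    def test_targetless_drug_reported_separately(self, five_drug_records, small_mapping):
        part = partition_drugs(five_drug_records, small_mapping)
        assert "DB00005" in part.excluded
        assert "DB00005" not in part.all_drugs

    def test_sizes_on_constructed_fixture(self, small_mapping):
        records = []
        for i in range(4):  # illicit
            records.append(make_drug(f"DBI{i}", groups=("illicit",), targets=("P11111",)))
        for i in range(6):  # related via the same gene
            records.append(make_drug(f"DBR{i}", targets=("P11111", "P44444")))
        for i in range(10):  # other
            records.append(make_drug(f"DBO{i}", targets=("P55555",)))
        part = partition_drugs(records, small_mapping)
        assert (len(part.illicit), len(part.illicit_related), len(part.other)) == (4, 6, 10)

    def test_partition_is_disjoint_and_exhaustive(self, five_drug_records, small_mapping):
        part = partition_drugs(five_drug_records, small_mapping)
        assert part.illicit & part.illicit_related == frozenset()
        assert part.illicit & part.other == frozenset()
        assert part.illicit_related & part.other == frozenset()
        targeted = {"DB00001", "DB00002", "DB00003", "DB00004"}
        assert part.all_drugs == targeted


class TestLabels:
    def test_annotation_labels_drugs_and_genes(self, five_drug_records, small_mapping):
        part = partition_drugs(five_drug_records, small_mapping)
        net = annotate_set_labels(build_network(five_drug_records, small_mapping), part)
        assert net.node_set_label["DB00001"] == "illicit"
        assert net.node_set_label["DB00003"] == "illicit-related"
        assert net.node_set_label["DB00004"] == "other"
        assert net.node_set_label["OPRM1"] == "illicit-target"
        assert net.node_set_label["ESR1"] == "other-target"

    def test_overlapping_node_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            BipartiteNetwork(frozenset({"X"}), frozenset({"X"}), frozenset())
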