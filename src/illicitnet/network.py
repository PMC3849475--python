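"""Construction and partitioning of bipartite drug-target networks.

Three networks are built from a parsed drug collection and a UniProt ->
gene-symbol mapping:

* the *illicit* network — drugs carrying the "illicit" legal-status tag
  and the genes they target;
* the *illicit-extended* network — the illicit network plus every
  non-illicit drug sharing at least one target gene with an illicit
  drug, with those drugs' edges restricted to the illicit target genes;
* the *full* network — every target-bearing drug and every targeted gene.

Gene identity is the mapped gene symbol: two UniProt accessions mapping
to one symbol are a single node, and repeated pharmacological actions
between one drug and one gene collapse to a single unweighted edge.
Targets lacking a mapping-table entry are dropped from networks but are
counted in a :class:`MappingReport` so the attrition is auditable.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .io import DrugRecord, GeneTarget

logger = logging.getLogger(__name__)

__all__ = [
    "BipartiteNetwork",
    "DrugSetPartition",
    "MappingReport",
    "mapped_genes",
    "mapping_report",
    "select_illicit",
    "build_network",
    "find_illicit_related",
    "build_extended",
    "partition_drugs",
    "annotate_set_labels",
]


@dataclass(frozen=True)
class BipartiteNetwork:
    """An undirected bipartite drug-gene network.

    ``node_set_label`` assigns each drug one of {"illicit",
    "illicit-related", "other"} and each gene one of {"illicit-target",
    "other-target"}; it may be empty until :func:`annotate_set_labels`
    is applied.
    """

    drug_nodes: frozenset[str]
    gene_nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]  # (drug_id, gene_symbol)
    node_set_label: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.drug_nodes & self.gene_nodes
        if overlap:
            raise ValueError(f"drug and gene node sets overlap: {sorted(overlap)[:5]}")
        for d, g in self.edges:
            if d not in self.drug_nodes or g not in self.gene_nodes:
                raise ValueError(f"edge ({d!r}, {g!r}) joins undeclared nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.drug_nodes) + len(self.gene_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def mean_drug_degree(self) -> float:
        """Average number of target genes per drug (edges / drugs)."""
        return self.n_edges / len(self.drug_nodes) if self.drug_nodes else 0.0

    def mean_gene_degree(self) -> float:
        """Average number of drugs per target gene (edges / genes)."""
        return self.n_edges / len(self.gene_nodes) if self.gene_nodes else 0.0

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for d in sorted(self.drug_nodes):
            g.add_node(d, kind="drug", bipartite=0, set_label=self.node_set_label.get(d, ""))
        for s in sorted(self.gene_nodes):
            g.add_node(s, kind="gene", bipartite=1, set_label=self.node_set_label.get(s, ""))
        g.add_edges_from(sorted(self.edges))
        return g

    def is_subgraph_of(self, other: "BipartiteNetwork") -> bool:
        return (
            self.drug_nodes <= other.drug_nodes
            and self.gene_nodes <= other.gene_nodes
            and self.edges <= other.edges
        )


@dataclass(frozen=True)
class DrugSetPartition:
    """Disjoint partition of target-bearing drugs.

    ``excluded`` holds drugs that had no mappable human target and
    therefore belong to none of the three analysis sets; it is reported
    alongside the partition rather than silently dropped.
    """

    illicit: frozenset[str]
    illicit_related: frozenset[str]
    other: frozenset[str]
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        sets = [self.illicit, self.illicit_related, self.other]
        for i, a in enumerate(sets):
            for b in sets[i + 1 :]:
                if a & b:
                    raise ValueError("partition sets must be pairwise disjoint")

    @property
    def all_drugs(self) -> frozenset[str]:
        return self.illicit | self.illicit_related | self.other

    def label_of(self, drug_id: str) -> str:
        if drug_id in self.illicit:
            return "illicit"
        if drug_id in self.illicit_related:
            return "illicit-related"
        return "other"


@dataclass
class MappingReport:
    """Audit of target accessions lost at the mapping step."""

    unmapped_accessions: Counter = field(default_factory=Counter)
    drugs_without_mapped_targets: set[str] = field(default_factory=set)
    non_human_targets_dropped: int = 0

    @property
    def n_unmapped(self) -> int:
        return sum(self.unmapped_accessions.values())


def mapped_genes(
    record: DrugRecord,
    mapping: Mapping[str, GeneTarget],
    report: MappingReport | None = None,
) -> list[str]:
    """Human target gene symbols of one drug, deduplicated, file order.

    Non-human targets are filtered out first (case-insensitive species
    match on "Humans"); accessions absent from the mapping are skipped
    and, if a report is supplied, tallied there.
    """
    symbols: list[str] = []
    seen: set[str] = set()
    for ref in record.target_refs:
        if not ref.is_human:
            if report is not None:
                report.non_human_targets_dropped += 1
            continue
        gt = mapping.get(ref.uniprot_acc)
        if gt is None:
            if report is not None:
                report.unmapped_accessions[ref.uniprot_acc] += 1
            continue
        if gt.gene_symbol not in seen:
            seen.add(gt.gene_symbol)
            symbols.append(gt.gene_symbol)
    return symbols


def mapping_report(records: Iterable[DrugRecord], mapping: Mapping[str, GeneTarget]) -> MappingReport:
    """Tally unmapped accessions and drugs left without any mapped target."""
    report = MappingReport()
    for rec in records:
        if not mapped_genes(rec, mapping, report):
            report.drugs_without_mapped_targets.add(rec.drug_id)
    return report


def select_illicit(records: Iterable[DrugRecord]) -> frozenset[str]:
    """Drugs whose legal-status groups include "illicit".

    A drug may hold other statuses (e.g. "approved") simultaneously.
    """
    return frozenset(r.drug_id for r in records if r.is_illicit)


def _gene_sets(
    records: Iterable[DrugRecord], mapping: Mapping[str, GeneTarget]
) -> dict[str, list[str]]:
    """drug_id -> mapped human gene symbols, only drugs with >= 1 mapped gene."""
    out: dict[str, list[str]] = {}
    for rec in records:
        genes = mapped_genes(rec, mapping)
        if genes:
            out[rec.drug_id] = genes
    return out


def build_network(
    records: Iterable[DrugRecord],
    mapping: Mapping[str, GeneTarget],
    drug_filter: set[str] | frozenset[str] | None = None,
) -> BipartiteNetwork:
    """Build a bipartite network over (optionally filtered) drugs.

    Drug nodes are restricted to drugs passing the filter that have at
    least one mapped human target; gene nodes to genes targeted by at
    least one included drug.  Edges are deduplicated at the
    (drug, gene-symbol) level.
    """
    records = list(records)
    gene_sets = _gene_sets(records, mapping)
    edges = set()
    for drug_id, genes in gene_sets.items():
        if drug_filter is not None and drug_id not in drug_filter:
            continue
        for g in genes:
            edges.add((drug_id, g))
    net = BipartiteNetwork(
        drug_nodes=frozenset(d for d, _ in edges),
        gene_nodes=frozenset(g for _, g in edges),
        edges=frozenset(edges),
    )
    if net.n_edges == 0:
        logger.warning("built an empty network (no drug passed the filter with mapped targets)")
    return net


def find_illicit_related(
    records: Iterable[DrugRecord],
    mapping: Mapping[str, GeneTarget],
    illicit_ids: frozenset[str] | set[str],
) -> frozenset[str]:
    """Non-illicit drugs sharing >= 1 mapped target gene with an illicit drug."""
    gene_sets = _gene_sets(records, mapping)
    illicit_genes = set()
    for drug_id in illicit_ids:
        illicit_genes.update(gene_sets.get(drug_id, ()))
    related = {
        drug_id
        for drug_id, genes in gene_sets.items()
        if drug_id not in illicit_ids and illicit_genes.intersection(genes)
    }
    return frozenset(related)


def build_extended(
    records: Iterable[DrugRecord],
    mapping: Mapping[str, GeneTarget],
    illicit_ids: frozenset[str] | set[str],
) -> BipartiteNetwork:
    """Build the illicit-extended network.

    Gene nodes are exactly the illicit target genes; drug nodes are the
    illicit drugs plus the illicit-related drugs; edges of related drugs
    are restricted to illicit target genes, so the illicit network is an
    exact subgraph of the result.
    """
    records = list(records)
    gene_sets = _gene_sets(records, mapping)
    illicit_genes: set[str] = set()
    for drug_id in illicit_ids:
        illicit_genes.update(gene_sets.get(drug_id, ()))
    related = find_illicit_related(records, mapping, frozenset(illicit_ids))
    edges = set()
    for drug_id, genes in gene_sets.items():
        if drug_id in illicit_ids:
            edges.update((drug_id, g) for g in genes)
        elif drug_id in related:
            edges.update((drug_id, g) for g in genes if g in illicit_genes)
    return BipartiteNetwork(
        drug_nodes=frozenset(d for d, _ in edges),
        gene_nodes=frozenset(g for _, g in edges),
        edges=frozenset(edges),
    )


def partition_drugs(
    records: Iterable[DrugRecord], mapping: Mapping[str, GeneTarget]
) -> DrugSetPartition:
    """Partition target-bearing drugs into illicit / illicit-related / other.

    Drugs without any mapped human target fall into ``excluded``.
    """
    records = list(records)
    gene_sets = _gene_sets(records, mapping)
    illicit_all = select_illicit(records)
    illicit = frozenset(d for d in illicit_all if d in gene_sets)
    related = find_illicit_related(records, mapping, illicit)
    other = frozenset(d for d in gene_sets if d not in illicit and d not in related)
    excluded = frozenset(r.drug_id for r in records if r.drug_id not in gene_sets)
    return DrugSetPartition(illicit=illicit, illicit_related=related, other=other, excluded=excluded)


def annotate_set_labels(net: BipartiteNetwork, partition: DrugSetPartition) -> BipartiteNetwork:
    """Return a copy of the network with drug/gene set labels filled in.

    Genes targeted by at least one illicit drug (within this network)
    are labelled "illicit-target", the rest "other-target".
    """
    illicit_genes = {g for d, g in net.edges if d in partition.illicit}
    labels: dict[str, str] = {}
    for d in net.drug_nodes:
        labels[d] = partition.label_of(d)
    for g in net.gene_nodes:
        labels[g] = "illicit-target" if g in illicit_genes else "other-target"
    return BipartiteNetwork(net.drug_nodes, net.gene_nodes, net.edges, labels)
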