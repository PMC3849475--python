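"""Readers and writers for the drug-record dialect and network formats.

Reads a minimal DrugBank-style XML dialect (accession, name, legal-status
groups, categories, ATC codes, protein targets with UniProtKB accessions)
into :class:`DrugRecord` objects, loads UniProt-to-gene mapping tables,
and round-trips edge lists, SIF and GraphML exports of the bipartite
networks.  Parsing is lossless for the dialect fields: serializing a
parsed collection and re-parsing reproduces identical records.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import networkx as nx
import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

ATC_CODE_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")
DRUG_ID_RE = re.compile(r"^DB\d+$")

__all__ = [
    "DrugRecord",
    "TargetRef",
    "GeneTarget",
    "ATC_CODE_RE",
    "parse_drugbank",
    "write_drugbank",
    "load_gene_mapping",
    "read_edge_list",
    "write_edge_list",
    "export_sif",
    "export_graphml",
]


@dataclass(frozen=True)
class TargetRef:
    """A protein target reference inside one drug record."""

    uniprot_acc: str
    species: str = "Humans"

    def __post_init__(self) -> None:
        if not self.uniprot_acc:
            raise ValueError("uniprot_acc must be non-empty")

    @property
    def is_human(self) -> bool:
        return self.species.strip().lower() == "humans"


@dataclass(frozen=True)
class GeneTarget:
    """A mapped protein target: UniProt accession, gene symbol, Entrez id."""

    uniprot_acc: str
    gene_symbol: str
    entrez_id: int


@dataclass(frozen=True)
class DrugRecord:
    """One drug: identity, legal-status groups, categories, ATC codes, targets.

    ``groups`` holds lower-cased legal-status tags ("approved", "illicit",
    ...); membership tests are therefore case-insensitive with respect to
    the source file.  ``target_refs`` preserves file order with duplicate
    accessions removed.
    """

    drug_id: str
    name: str
    groups: frozenset[str] = frozenset()
    categories: frozenset[str] = frozenset()
    atc_codes: tuple[str, ...] = ()
    target_refs: tuple[TargetRef, ...] = ()

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValueError("drug_id must be non-empty")
        for code in self.atc_codes:
            if not ATC_CODE_RE.match(code):
                raise ValueError(
                    f"drug {self.drug_id}: malformed ATC code {code!r} "
                    "(expected letter, 2 digits, 2 letters, 2 digits)"
                )
        seen = [t.uniprot_acc for t in self.target_refs]
        if len(seen) != len(set(seen)):
            raise ValueError(f"drug {self.drug_id}: duplicate target accessions")

    @property
    def is_illicit(self) -> bool:
        return "illicit" in self.groups

    def human_accessions(self) -> tuple[str, ...]:
        """Accessions of human targets, file order, deduplicated."""
        return tuple(t.uniprot_acc for t in self.target_refs if t.is_human)


def _dedup_keep_order(items: Iterable) -> list:
    seen = set()
    out = []
    for x in items:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out


def parse_drugbank(source: str | Path | IO) -> list[DrugRecord]:
    """Parse dialect XML into drug records, preserving file order.

    Duplicate target accessions within one drug are collapsed to the
    first occurrence; a duplicated drug accession across records is a
    validation error.  Malformed XML raises ``lxml``'s syntax error,
    which names the offending line.
    """
    tree = etree.parse(source)
    root = tree.getroot()
    records: list[DrugRecord] = []
    seen_ids: set[str] = set()
    for drug_el in root.iterfind("drug"):
        drug_id = (drug_el.findtext("drugbank-id") or "").strip()
        name = (drug_el.findtext("name") or "").strip()
        groups = frozenset(
            g.text.strip().lower() for g in drug_el.iterfind("groups/group") if g.text
        )
        categories = frozenset(
            c.text.strip() for c in drug_el.iterfind("categories/category") if c.text
        )
        atc_codes = tuple(
            _dedup_keep_order(
                el.get("code", "").strip()
                for el in drug_el.iterfind("atc-codes/atc-code")
                if el.get("code")
            )
        )
        target_refs = []
        seen_acc: set[str] = set()
        for poly in drug_el.iterfind("targets/target/polypeptide"):
            acc = (poly.get("uniprot-id") or "").strip()
            if not acc or acc in seen_acc:
                continue
            seen_acc.add(acc)
            target_refs.append(TargetRef(acc, poly.get("species", "").strip()))
        record = DrugRecord(
            drug_id=drug_id,
            name=name,
            groups=groups,
            categories=categories,
            atc_codes=atc_codes,
            target_refs=tuple(target_refs),
        )
        if record.drug_id in seen_ids:
            raise ValueError(f"duplicate drug accession {record.drug_id!r}")
        seen_ids.add(record.drug_id)
        records.append(record)
    return records


def write_drugbank(records: Iterable[DrugRecord], target: str | Path | IO | None = None) -> bytes:
    """Serialize records back to dialect XML (deterministic byte output).

    Set-valued fields are written in sorted order so that the same
    records always serialize to the same bytes.  Returns the XML bytes;
    also writes them to ``target`` when given.
    """
    root = etree.Element("drugbank")
    for rec in records:
        drug_el = etree.SubElement(root, "drug")
        etree.SubElement(drug_el, "drugbank-id").text = rec.drug_id
        etree.SubElement(drug_el, "name").text = rec.name
        groups_el = etree.SubElement(drug_el, "groups")
        for g in sorted(rec.groups):
            etree.SubElement(groups_el, "group").text = g
        cats_el = etree.SubElement(drug_el, "categories")
        for c in sorted(rec.categories):
            etree.SubElement(cats_el, "category").text = c
        atc_el = etree.SubElement(drug_el, "atc-codes")
        for code in rec.atc_codes:
            etree.SubElement(atc_el, "atc-code", code=code)
        targets_el = etree.SubElement(drug_el, "targets")
        for t in rec.target_refs:
            target_el = etree.SubElement(targets_el, "target")
            etree.SubElement(
                target_el, "polypeptide", **{"uniprot-id": t.uniprot_acc, "species": t.species}
            )
    data = etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    if target is not None:
        if hasattr(target, "write"):
            target.write(data)
        else:
            Path(target).write_bytes(data)
    return data


def load_gene_mapping(source: str | Path | IO) -> dict[str, GeneTarget]:
    """Load a UniProt accession -> gene symbol/Entrez id table.

    Expects a TSV with header ``uniprot_acc, gene_symbol, entrez_id``.
    Exact duplicate rows collapse silently; the same accession mapped to
    two different symbols is a validation error (the mapping must be
    functional).  An empty table yields an empty mapping with a warning.
    """
    df = pd.read_csv(source, sep="\t", dtype={"uniprot_acc": str, "gene_symbol": str})
    required = {"uniprot_acc", "gene_symbol", "entrez_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"mapping table must have columns {sorted(required)}, got {list(df.columns)}")
    if df.empty:
        logger.warning("gene mapping table is empty")
        return {}
    mapping: dict[str, GeneTarget] = {}
    for row in df.itertuples(index=False):
        gt = GeneTarget(row.uniprot_acc, row.gene_symbol, int(row.entrez_id))
        prev = mapping.get(gt.uniprot_acc)
        if prev is not None and prev.gene_symbol != gt.gene_symbol:
            raise ValueError(
                f"accession {gt.uniprot_acc} maps to both {prev.gene_symbol!r} "
                f"and {gt.gene_symbol!r}"
            )
        mapping[gt.uniprot_acc] = gt
    return mapping


def write_gene_mapping(mapping: Mapping[str, GeneTarget], target: str | Path | IO) -> None:
    """Write a mapping back to its three-column TSV form (sorted by accession)."""
    df = pd.DataFrame(
        [(g.uniprot_acc, g.gene_symbol, g.entrez_id) for g in mapping.values()],
        columns=["uniprot_acc", "gene_symbol", "entrez_id"],
    ).sort_values("uniprot_acc")
    df.to_csv(target, sep="\t", index=False)


def read_edge_list(source: str | Path | IO, dedup: bool = False) -> list[tuple[str, str]]:
    """Read a drug-gene edge list TSV into (drug_id, gene_symbol) pairs.

    The format is three tab-separated columns ``drug_id, drug_name,
    gene_symbol`` with a header row.  A row with a missing value raises
    an error naming the (1-based, data) row number.  With ``dedup`` a
    repeated pair is kept once; otherwise duplicates are preserved.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"drug_id", "gene_symbol"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge list must have columns {sorted(required)}, got {list(df.columns)}")
    bad = df.index[df[["drug_id", "gene_symbol"]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"edge list row {bad[0] + 1} has a missing column")
    pairs = list(zip(df["drug_id"], df["gene_symbol"]))
    return _dedup_keep_order(pairs) if dedup else pairs


def write_edge_list(network, target: str | Path | IO, drug_names: Mapping[str, str] | None = None) -> None:
    """Write a network's edges as the three-column TSV (sorted, deterministic)."""
    names = drug_names or {}
    rows = sorted((d, names.get(d, ""), g) for d, g in network.edges)
    pd.DataFrame(rows, columns=["drug_id", "drug_name", "gene_symbol"]).to_csv(
        target, sep="\t", index=False
    )


def export_sif(network, target: str | Path | IO) -> None:
    """Write the network in SIF form: ``drug<TAB>targets<TAB>gene`` lines."""
    lines = [f"{d}\ttargets\t{g}\n" for d, g in sorted(network.edges)]
    if hasattr(target, "write"):
        target.writelines(lines)
    else:
        Path(target).write_text("".join(lines))


def export_graphml(
    network,
    target: str | Path | IO,
    node_attributes: Mapping[str, Mapping[str, object]] | None = None,
) -> None:
    """Write the network as GraphML with typed node attributes.

    ``node_attributes`` maps node id to a dict of attributes (degree,
    betweenness, is_hub, is_bridge, ...); an attribute entry for a node
    absent from the network is an error.  Node kind ("drug"/"gene") and
    the set label are always attached.
    """
    g = network.to_networkx()
    if node_attributes:
        unknown = set(node_attributes) - set(g.nodes)
        if unknown:
            raise ValueError(f"attributes reference unknown nodes: {sorted(unknown)[:5]}")
        for node, attrs in node_attributes.items():
            for key, value in attrs.items():
                if isinstance(value, (bool,)):
                    value = bool(value)
                g.nodes[node][key] = value
    nx.write_graphml(g, target)
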