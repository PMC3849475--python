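"""Seeded generator of drug-target datasets with planted ground truth.

The generator emulates the qualitative structure of a curated drug
database slice: drugs organised in a few therapeutic clusters
(depressants, stimulants, analgesics, steroids by default), each
cluster targeting its own pool of genes, a minority of drugs flagged
"illicit" (concentrated in the depressant cluster), ATC codes drawn
from cluster-specific second-sublevel pools, designated hub drugs with
boosted edge probability (supplying heavy-tailed degrees), and planted
*bridge genes* that connect two clusters and should dominate
betweenness.

Edges follow a planted-partition bipartite Bernoulli model: within a
cluster each drug-gene pair is an edge with probability ``p_within``
(hub drugs: ``p_within * hub_boost``, capped at 1), across clusters
with probability ``p_between``.  Each bridge gene additionally draws
within-cluster-rate edges into both of its clusters, with at least two
guaranteed on each side.  All randomness flows through one seeded
generator in a fixed order, so a given config yields byte-identical
XML every time.
"""

from __future__ import annotations

import dataclasses
import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .io import DrugRecord, GeneTarget, TargetRef, write_drugbank, write_gene_mapping

__all__ = [
    "ClusterSpec",
    "SyntheticConfig",
    "GroundTruth",
    "default_config",
    "generate",
    "generate_candidate_list",
    "write_dataset",
]


@dataclass(frozen=True)
class ClusterSpec:
    """One therapeutic cluster of the planted-partition model."""

    name: str
    n_drugs: int = 20
    n_genes: int = 15
    p_within: float = 0.3
    illicit_fraction: float = 0.15
    atc_pool: tuple[tuple[str, float], ...] = ()
    n_hub_drugs: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_within <= 1.0 and 0.0 <= self.illicit_fraction <= 1.0):
            raise ValueError(f"cluster {self.name}: probabilities must lie in [0, 1]")
        if self.n_hub_drugs > self.n_drugs:
            raise ValueError(f"cluster {self.name}: more hub drugs than drugs")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generator configuration; ``seed`` governs all randomness."""

    clusters: tuple[ClusterSpec, ...]
    p_between: float = 0.01
    n_bridge_genes: int = 3
    bridge_pairs: tuple[tuple[str, str], ...] = ()
    hub_boost: float = 3.0
    atc_coverage: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        names = [c.name for c in self.clusters]
        if len(names) != len(set(names)):
            raise ValueError("cluster names must be unique")
        if not (0.0 <= self.p_between <= 1.0 and 0.0 <= self.atc_coverage <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        for a, b in self.bridge_pairs:
            for side in (a, b):
                if side not in names:
                    raise ValueError(f"bridge pair references unknown cluster {side!r}")
        if self.n_bridge_genes > 0:
            if not self.bridge_pairs:
                raise ValueError("bridge genes requested but no bridge_pairs given")
            by_name = {c.name: c for c in self.clusters}
            for a, b in self.bridge_pairs:
                if by_name[a].n_drugs < 2 or by_name[b].n_drugs < 2:
                    raise ValueError(
                        f"bridge pair ({a}, {b}) infeasible: each side needs >= 2 drugs"
                    )


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: cluster assignments, hubs, bridges, enrichments."""

    cluster_of: Mapping[str, str]  # node id -> cluster name
    hub_drugs: tuple[str, ...]
    bridge_genes: tuple[str, ...]
    enriched_pairs: tuple[tuple[str, str], ...]  # (cluster name, ATC second sublevel)
    illicit_drugs: tuple[str, ...]
    illicit_target_genes: tuple[str, ...]
    gene_symbols: tuple[str, ...]

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["cluster_of"] = dict(sorted(self.cluster_of.items()))
        return json.dumps(payload, indent=2, sort_keys=True)


def default_config(seed: int = 0) -> SyntheticConfig:
    """The four-cluster study configuration.

    Depressants carry a five-fold higher illicit fraction than the
    other clusters (0.75 vs 0.15), mirroring the strong concentration
    of illicit compounds among sedative/hypnotic drug classes; each
    cluster's ATC pool is dominated by one second sublevel, so every
    cluster plants one (cluster, category) enrichment.  Three bridge
    genes chain the clusters depressants-stimulants-analgesics-steroids.
    """
    clusters = (
        ClusterSpec("depressants", illicit_fraction=0.75, atc_pool=(("N05", 0.85), ("N03", 0.15))),
        ClusterSpec("stimulants", illicit_fraction=0.15, atc_pool=(("N06", 0.7), ("A08", 0.3))),
        ClusterSpec("analgesics", illicit_fraction=0.15, atc_pool=(("N02", 0.8), ("N01", 0.2))),
        ClusterSpec("steroids", illicit_fraction=0.15, atc_pool=(("G03", 0.7), ("H02", 0.2), ("D07", 0.1))),
    )
    return SyntheticConfig(
        clusters=clusters,
        bridge_pairs=(
            ("depressants", "stimulants"),
            ("stimulants", "analgesics"),
            ("analgesics", "steroids"),
        ),
        seed=seed,
    )


_LETTERS = np.array(list(string.ascii_uppercase))


def _draw_atc_codes(rng: np.random.Generator, pool, coverage: float) -> tuple[str, ...]:
    if not pool or rng.random() >= coverage:
        return ()
    codes = []
    n_codes = 1 + int(rng.random() < 0.3)
    levels = [c for c, _ in pool]
    weights = np.array([w for _, w in pool], dtype=float)
    weights = weights / weights.sum()
    for _ in range(n_codes):
        level = str(rng.choice(levels, p=weights))
        suffix = "".join(rng.choice(_LETTERS, size=2)) + f"{rng.integers(1, 100):02d}"
        codes.append(level + suffix)
    # same second sublevel twice is fine; identical full codes collapse
    out = []
    for c in codes:
        if c not in out:
            out.append(c)
    return tuple(out)


def generate(
    config: SyntheticConfig,
) -> tuple[list[DrugRecord], dict[str, GeneTarget], GroundTruth]:
    """Generate a drug collection, gene mapping, and its ground truth.

    Deterministic in ``config`` (including its seed): the same config
    always yields identical records, hence identical serialized XML.
    """
    rng = np.random.default_rng(config.seed)

    # ---- identifiers -------------------------------------------------
    drug_ids: list[str] = []
    drug_cluster: list[str] = []
    gene_symbols: list[str] = []
    gene_cluster: list[str] = []
    for cluster in config.clusters:
        prefix = cluster.name[:3].upper()
        for i in range(cluster.n_drugs):
            drug_ids.append(f"DB{len(drug_ids) + 1:05d}")
            drug_cluster.append(cluster.name)
        for i in range(cluster.n_genes):
            gene_symbols.append(f"{prefix}G{i + 1:02d}")
            gene_cluster.append(cluster.name)

    n_drugs, n_genes = len(drug_ids), len(gene_symbols)
    cluster_names = [c.name for c in config.clusters]
    by_name = {c.name: c for c in config.clusters}

    hub_drugs: list[str] = []
    hub_mask = np.zeros(n_drugs, dtype=bool)
    offset = 0
    for cluster in config.clusters:
        for i in range(cluster.n_hub_drugs):
            hub_mask[offset + i] = True
            hub_drugs.append(drug_ids[offset + i])
        offset += cluster.n_drugs

    # ---- planted-partition edge matrix -------------------------------
    prob = np.full((n_drugs, n_genes), config.p_between)
    d_off = 0
    for cluster in config.clusters:
        g_idx = [j for j, c in enumerate(gene_cluster) if c == cluster.name]
        rows = slice(d_off, d_off + cluster.n_drugs)
        prob[rows, g_idx[0] : g_idx[-1] + 1] = cluster.p_within
        d_off += cluster.n_drugs
    prob[hub_mask] = np.minimum(prob[hub_mask] * config.hub_boost, 1.0)
    adjacency = rng.random((n_drugs, n_genes)) < prob

    # ---- bridge genes -------------------------------------------------
    bridge_genes: list[str] = []
    bridge_cols = []
    for i in range(config.n_bridge_genes):
        pair = config.bridge_pairs[i % len(config.bridge_pairs)]
        symbol = f"BRG{i + 1}"
        bridge_genes.append(symbol)
        gene_symbols.append(symbol)
        gene_cluster.append("+".join(pair))
        col = np.zeros(n_drugs, dtype=bool)
        for side in pair:
            idx = np.array([j for j, c in enumerate(drug_cluster) if c == side])
            # a bridge gene is a hub-grade node of both its clusters: drugs of
            # two classes converge on it, which is what makes it a bridge
            p_attach = min(1.0, by_name[side].p_within * config.hub_boost)
            hits = rng.random(idx.size) < p_attach
            if hits.sum() < 2:  # guarantee the bridge actually spans the cluster
                missing = 2 - int(hits.sum())
                extra = rng.choice(np.flatnonzero(~hits), size=missing, replace=False)
                hits[extra] = True
            col[idx[hits]] = True
        bridge_cols.append(col)
    if bridge_cols:
        adjacency = np.hstack([adjacency, np.column_stack(bridge_cols)])

    # ---- gene mapping -------------------------------------------------
    mapping: dict[str, GeneTarget] = {}
    acc_of: dict[str, str] = {}
    for j, symbol in enumerate(gene_symbols):
        acc = f"P{10000 + j}"
        acc_of[symbol] = acc
        mapping[acc] = GeneTarget(acc, symbol, 1000 + j)

    # ---- drug records -------------------------------------------------
    records: list[DrugRecord] = []
    illicit_drugs: list[str] = []
    for i, drug_id in enumerate(drug_ids):
        cluster = by_name[drug_cluster[i]]
        is_illicit = bool(rng.random() < cluster.illicit_fraction)
        groups = {"illicit"} if is_illicit else {"approved"}
        if is_illicit and rng.random() < 0.5:
            groups.add("approved")
        elif not is_illicit and rng.random() < 0.2:
            groups.add("experimental")
        atc_codes = _draw_atc_codes(rng, cluster.atc_pool, config.atc_coverage)
        targets = tuple(
            TargetRef(acc_of[gene_symbols[j]], "Humans")
            for j in np.flatnonzero(adjacency[i])
        )
        if is_illicit:
            illicit_drugs.append(drug_id)
        records.append(
            DrugRecord(
                drug_id=drug_id,
                name=f"{cluster.name}-compound-{i + 1}",
                groups=frozenset(groups),
                categories=frozenset({cluster.name.capitalize()}),
                atc_codes=atc_codes,
                target_refs=targets,
            )
        )

    illicit_target_genes = sorted(
        {
            gene_symbols[j]
            for i in range(n_drugs)
            if drug_ids[i] in set(illicit_drugs)
            for j in np.flatnonzero(adjacency[i])
        }
    )
    enriched_pairs = tuple(
        (c.name, max(c.atc_pool, key=lambda cw: cw[1])[0]) for c in config.clusters if c.atc_pool
    )
    cluster_of = dict(zip(drug_ids, drug_cluster)) | dict(zip(gene_symbols, gene_cluster))
    truth = GroundTruth(
        cluster_of=cluster_of,
        hub_drugs=tuple(hub_drugs),
        bridge_genes=tuple(bridge_genes),
        enriched_pairs=enriched_pairs,
        illicit_drugs=tuple(illicit_drugs),
        illicit_target_genes=tuple(illicit_target_genes),
        gene_symbols=tuple(gene_symbols),
    )
    return records, mapping, truth


def generate_candidate_list(
    truth: GroundTruth,
    overlap_count: int = 17,
    decoy_count: int = 45,
    seed: int = 0,
) -> list[str]:
    """An external candidate-gene list with a known planted overlap.

    Exactly ``overlap_count`` genes come from the illicit target set;
    the decoys are genes outside it (other generated genes first, then
    invented symbols if the dataset runs out).  Defaults mirror a
    62-gene addiction candidate set of which 17 fall in the illicit
    target network.
    """
    rng = np.random.default_rng(seed)
    in_set = sorted(truth.illicit_target_genes)
    if overlap_count > len(in_set):
        raise ValueError(
            f"requested overlap {overlap_count} exceeds the {len(in_set)} illicit target genes"
        )
    out_pool = sorted(set(truth.gene_symbols) - set(in_set))
    chosen = list(rng.choice(in_set, size=overlap_count, replace=False)) if overlap_count else []
    n_real_decoys = min(decoy_count, len(out_pool))
    decoys = list(rng.choice(out_pool, size=n_real_decoys, replace=False)) if n_real_decoys else []
    decoys += [f"NOVEL{i + 1}" for i in range(decoy_count - n_real_decoys)]
    candidates = [str(g) for g in chosen + decoys]
    rng.shuffle(candidates)
    return candidates


def write_dataset(
    records,
    mapping,
    truth: GroundTruth,
    config: SyntheticConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the generated dataset: XML, mapping TSV, truth JSON, config YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "xml": out / "drugs.xml",
        "mapping": out / "gene_mapping.tsv",
        "ground_truth": out / "ground_truth.json",
        "config": out / "config.yaml",
    }
    write_drugbank(records, paths["xml"])
    write_gene_mapping(mapping, paths["mapping"])
    paths["ground_truth"].write_text(truth.to_json() + "\n")
    paths["config"].write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=True))
    return paths
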