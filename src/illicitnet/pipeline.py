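"""End-to-end orchestration: from records to networks, tables and summary.

A :class:`RunConfig` names either an input XML + mapping table or a
synthetic generator configuration, plus cutoff settings, alpha levels
and an output directory.  :func:`run_pipeline` then builds the three
networks, computes centralities with hub/bridge flags, runs the ATC
enrichment comparisons and degree-distribution tests, and writes a
deterministic bundle: edge lists, GraphML exports, centrality and
enrichment TSVs, paper-style report tables, and a ``summary.json``
whose bytes depend only on config and seed.

Averages are reported both unrounded and at one decimal (half-up),
because published round-offs occasionally disagree with the underlying
ratio; the summary keeps both so discrepancies stay visible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Sequence

from . import enrichment as enr
from . import io as dio
from . import network as netmod
from . import topology as topo
from .synthetic import SyntheticConfig, generate, write_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "report_tables",
    "format_count_pct",
    "round_half_up",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``xml_path`` and ``synthetic`` must be set.  A
    ``None`` cutoff means knee detection on the corresponding ranked
    distribution; a number reproduces a fixed published-style cutoff.
    """

    out_dir: str | Path
    xml_path: str | Path | None = None
    mapping_path: str | Path | None = None
    synthetic: SyntheticConfig | None = None
    candidate_path: str | Path | None = None
    gene_term_membership_path: str | Path | None = None
    pathway_membership_path: str | Path | None = None
    degree_cutoff: float | None = None
    betweenness_cutoff: float | None = None
    pair_convention: str = "unordered"
    alpha: float = 0.05
    alpha_adj: float = 0.05
    wilcoxon_exclude_illicit: bool = False
    full_betweenness: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.xml_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of xml_path and synthetic must be set")
        if self.xml_path is not None and self.mapping_path is None:
            raise ValueError("xml_path requires mapping_path")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 at one decimal rounds to 0.1)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_count_pct(count: int, total: int) -> str:
    """Render ``count`` with its percentage of ``total``: ``"24 (48.0)"``.

    A zero count renders as ``"0 (0)"`` (no decimal), matching the
    report-table convention for empty cells.
    """
    if count == 0:
        return "0 (0)"
    pct = 100.0 * count / total
    return f"{count} ({round_half_up(pct, 1):.1f})"


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class PipelineError(RuntimeError):
    """A stage failure carrying the stage name and input fingerprint."""

    def __init__(self, stage: str, fingerprint: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed (input {fingerprint[:12]}): {cause}")
        self.stage = stage
        self.fingerprint = fingerprint


def _cutoff(values, metric: str, manual: float | None) -> topo.CutoffDecision:
    if manual is not None:
        return topo.detect_cutoff(values, metric=metric, method="manual", manual_threshold=manual)
    return topo.detect_cutoff(values, metric=metric, method="knee")


def _network_summary(net: netmod.BipartiteNetwork) -> dict[str, Any]:
    return {
        "n_drugs": len(net.drug_nodes),
        "n_genes": len(net.gene_nodes),
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "mean_drug_degree": net.mean_drug_degree(),
        "mean_drug_degree_1dp": round_half_up(net.mean_drug_degree(), 1),
        "mean_gene_degree": net.mean_gene_degree(),
        "mean_gene_degree_1dp": round_half_up(net.mean_gene_degree(), 1),
    }


def _write_centrality(records: Sequence[topo.CentralityRecord], path: Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            (r.node_id, r.node_kind, r.degree, r.betweenness, r.is_hub, r.is_bridge)
            for r in records
        ],
        columns=["node_id", "node_kind", "degree", "betweenness", "is_hub", "is_bridge"],
    ).to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full analysis and write the output bundle.

    Returns the in-memory bundle: networks, partition, cutoff
    decisions, enrichment results and the summary dict that was written
    to ``summary.json``.  Identical config (including seed) produces a
    byte-identical bundle on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fingerprint = "-"

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise PipelineError(name, fingerprint, exc) from exc

        return wrap

    # ---- inputs -------------------------------------------------------
    if config.synthetic is not None:
        records, mapping, truth = stage("simulate")(generate, config.synthetic)
        dataset_dir = out / "dataset"
        write_dataset(records, mapping, truth, config.synthetic, dataset_dir)
        fingerprint = _sha256(dataset_dir / "drugs.xml")
        inputs = {"synthetic_seed": config.synthetic.seed, "xml_sha256": fingerprint}
    else:
        records = stage("parse")(dio.parse_drugbank, str(config.xml_path))
        mapping = stage("parse")(dio.load_gene_mapping, str(config.mapping_path))
        fingerprint = _sha256(config.xml_path)
        inputs = {
            "xml_sha256": fingerprint,
            "mapping_sha256": _sha256(config.mapping_path),
        }
        truth = None

    names = {r.drug_id: r.name for r in records}

    # ---- networks -----------------------------------------------------
    build = stage("build")
    partition = build(netmod.partition_drugs, records, mapping)
    illicit_net = build(netmod.build_network, records, mapping, partition.illicit)
    extended_net = build(netmod.build_extended, records, mapping, partition.illicit)
    full_net = build(netmod.build_network, records, mapping, None)
    illicit_net = netmod.annotate_set_labels(illicit_net, partition)
    extended_net = netmod.annotate_set_labels(extended_net, partition)
    full_net = netmod.annotate_set_labels(full_net, partition)
    assert illicit_net.is_subgraph_of(extended_net)

    nets = {"illicit": illicit_net, "extended": extended_net, "full": full_net}
    for key, net in nets.items():
        dio.write_edge_list(net, out / f"{key}_edges.tsv", names)

    # ---- topology -----------------------------------------------------
    t = stage("topology")
    degree_cutoffs: dict[str, topo.CutoffDecision] = {}
    centrality: dict[str, list[topo.CentralityRecord]] = {}
    betweenness_cutoff = None
    for key, net in nets.items():
        deg = topo.degree(net)
        degree_cutoffs[key] = t(_cutoff, deg.values(), "degree", config.degree_cutoff)
        if key == "full" and not config.full_betweenness:
            # betweenness of the full network is not used downstream;
            # skip the all-pairs computation unless explicitly requested
            hubs = topo.flag_hubs(net, degree_cutoffs[key])
            centrality[key] = [
                topo.CentralityRecord(
                    node,
                    "drug" if node in net.drug_nodes else "gene",
                    deg[node],
                    float("nan"),
                    node in hubs,
                    False,
                )
                for node in sorted(net.drug_nodes) + sorted(net.gene_nodes)
            ]
        else:
            btw = t(topo.betweenness, net, config.pair_convention)
            cut = t(_cutoff, btw.values(), "betweenness", config.betweenness_cutoff)
            if key == "extended":
                betweenness_cutoff = cut
            centrality[key] = t(
                topo.centrality_records,
                net,
                degree_cutoffs[key],
                cut,
                config.pair_convention,
            )
        _write_centrality(centrality[key], out / f"centrality_{key}.tsv")
        attrs = {
            r.node_id: {
                "degree": r.degree,
                "betweenness": r.betweenness,
                "is_hub": r.is_hub,
                "is_bridge": r.is_bridge,
            }
            for r in centrality[key]
        }
        dio.export_graphml(net, str(out / f"{key}.graphml"), attrs)
        dio.export_sif(net, out / f"{key}.sif")

    # ---- enrichment ---------------------------------------------------
    e = stage("enrich")
    memberships = enr.atc_memberships(records)
    annotated = enr.drugs_with_atc(records)
    atc_results = {}
    for set_name, drug_set in (
        ("illicit", partition.illicit),
        ("illicit_related", partition.illicit_related),
    ):
        a = drug_set & annotated
        b = partition.other & annotated
        if a and b:
            res = e(enr.enrich_drug_categories, a, b, memberships, config.alpha)
            atc_results[set_name] = res
            enr.write_results_table(res, out / f"enrichment_atc_{set_name}.tsv")

    gene_term_results = None
    if config.gene_term_membership_path:
        terms = enr.load_membership_table(str(config.gene_term_membership_path))
        illicit_genes = set(illicit_net.gene_nodes)
        other_genes = set(full_net.gene_nodes) - illicit_genes
        gene_term_results = e(
            enr.enrich_gene_terms_comparative, illicit_genes, other_genes, terms, config.alpha
        )
        enr.write_results_table(gene_term_results, out / "enrichment_gene_terms.tsv")

    pathway_results = None
    if config.pathway_membership_path:
        pathways = enr.load_membership_table(str(config.pathway_membership_path))
        universe = frozenset().union(*(p.members for p in pathways))
        pathway_results = e(
            enr.enrich_pathways_within_set,
            set(illicit_net.gene_nodes) & universe,
            pathways,
            universe,
            config.alpha_adj,
        )
        enr.write_results_table(pathway_results, out / "enrichment_pathways.tsv")

    # ---- degree comparisons -------------------------------------------
    deg_ill = topo.degree(illicit_net)
    deg_full = topo.degree(full_net)
    full_drugs = full_net.drug_nodes
    if config.wilcoxon_exclude_illicit:
        full_drugs = full_drugs - illicit_net.drug_nodes
    drug_test = topo.compare_degree_distributions(
        [deg_ill[d] for d in sorted(illicit_net.drug_nodes)],
        [deg_full[d] for d in sorted(full_drugs)],
    )
    full_genes = full_net.gene_nodes
    gene_test = topo.compare_degree_distributions(
        [deg_ill[g] for g in sorted(illicit_net.gene_nodes)],
        [deg_full[g] for g in sorted(full_genes)],
    )

    # ---- candidate overlap --------------------------------------------
    overlap = None
    if config.candidate_path:
        candidates = [
            line.strip()
            for line in Path(config.candidate_path).read_text().splitlines()
            if line.strip()
        ]
        overlap = e(
            enr.candidate_overlap_test,
            candidates,
            illicit_net.gene_nodes,
            full_net.gene_nodes,
        )

    # ---- summary ------------------------------------------------------
    summary: dict[str, Any] = {
        "inputs": inputs,
        "seed": config.seed,
        "conventions": {
            "pair_convention": config.pair_convention,
            "wilcoxon_exclude_illicit": config.wilcoxon_exclude_illicit,
            "alpha": config.alpha,
            "alpha_adj": config.alpha_adj,
        },
        "partition": {
            "n_illicit": len(partition.illicit),
            "n_illicit_related": len(partition.illicit_related),
            "n_other": len(partition.other),
            "n_excluded_no_mapped_target": len(partition.excluded),
        },
        "networks": {key: _network_summary(net) for key, net in nets.items()},
        "extended_node_identity": {
            "n_nodes": extended_net.n_nodes,
            "n_illicit_plus_related_plus_genes": len(extended_net.drug_nodes)
            + len(extended_net.gene_nodes),
        },
        "cutoffs": {
            "degree": {
                key: {"method": c.method, "threshold": c.threshold}
                for key, c in degree_cutoffs.items()
            },
            "betweenness_extended": (
                {"method": betweenness_cutoff.method, "threshold": betweenness_cutoff.threshold}
                if betweenness_cutoff
                else None
            ),
        },
        "hubs": {
            key: sum(r.is_hub for r in recs) for key, recs in centrality.items()
        },
        "bridges_extended": sum(r.is_bridge for r in centrality["extended"]),
        "wilcoxon": {
            "drug_degree": {"p": drug_test.p, "statistic": drug_test.statistic, "method": drug_test.method},
            "gene_degree": {"p": gene_test.p, "statistic": gene_test.statistic, "method": gene_test.method},
        },
    }
    if overlap is not None:
        summary["candidate_overlap"] = {
            "p": float(overlap.p),
            "p_point": float(overlap.p_point),
            "population": overlap.population,
            "successes": overlap.successes,
            "draws": overlap.draws,
            "observed": overlap.observed,
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    bundle = {
        "records": records,
        "mapping": mapping,
        "partition": partition,
        "networks": nets,
        "centrality": centrality,
        "degree_cutoffs": degree_cutoffs,
        "betweenness_cutoff": betweenness_cutoff,
        "atc_enrichment": atc_results,
        "gene_term_enrichment": gene_term_results,
        "pathway_enrichment": pathway_results,
        "wilcoxon": {"drug_degree": drug_test, "gene_degree": gene_test},
        "candidate_overlap": overlap,
        "summary": summary,
        "ground_truth": truth,
    }
    report = report_tables(bundle)
    (out / "report.md").write_text(report["markdown"])
    return bundle


def _enrichment_markdown(title: str, col_a: str, col_b: str, results, n_a: int, n_b: int) -> str:
    lines = [
        f"### {title}",
        "",
        f"| Category | {col_a} | {col_b} | p-value | adj. p |",
        "|---|---|---|---|---|",
    ]
    for r in results:
        if not r.significant:
            continue
        padj = f"{r.p_adj:.2g}" if r.p_adj is not None else ""
        lines.append(
            f"| {r.category_id} | {format_count_pct(r.count_a, n_a)} | "
            f"{format_count_pct(r.count_b, n_b)} | {r.p:.2g} | {padj} |"
        )
    lines.append("")
    return "\n".join(lines)


def report_tables(bundle: dict[str, Any]) -> dict[str, Any]:
    """Render the bundle's enrichment and census results as tables.

    Returns a dict with a ``markdown`` report and the per-table
    dataframes; counts are rendered as ``"count (pct)"`` with one
    half-up decimal, zero counts as ``"0 (0)"``.
    """
    import pandas as pd

    summary = bundle["summary"]
    parts = ["# Drug-target network analysis report", ""]
    census_rows = []
    for key, s in summary["networks"].items():
        census_rows.append(
            (key, s["n_drugs"], s["n_genes"], s["n_edges"],
             f"{s['mean_drug_degree_1dp']:.1f}", f"{s['mean_gene_degree_1dp']:.1f}")
        )
    census = pd.DataFrame(
        census_rows,
        columns=["network", "drugs", "genes", "edges", "mean drug degree", "mean gene degree"],
    )
    parts.append("## Network census\n")
    parts.append(census.to_markdown(index=False))
    parts.append("")

    n_other = summary["partition"]["n_other"]
    tables = {"census": census}
    for set_name, results in (bundle.get("atc_enrichment") or {}).items():
        if not results:
            continue
        # percentages in the stored results are already on the annotated sets
        n_a = round(results[0].count_a / (results[0].pct_a / 100.0)) if results[0].count_a else None
        for r in results:
            if r.count_a:
                n_a = round(r.count_a / (r.pct_a / 100.0))
                break
        n_b = None
        for r in results:
            if r.count_b:
                n_b = round(r.count_b / (r.pct_b / 100.0))
                break
        if n_a is None or n_b is None:
            continue
        parts.append(
            _enrichment_markdown(
                f"ATC second-sublevel categories enriched in {set_name.replace('_', '-')} drugs",
                f"# of {set_name.replace('_', '-')} drugs (%)",
                "# of other drugs (%)",
                results,
                n_a,
                n_b,
            )
        )
        tables[f"atc_{set_name}"] = pd.DataFrame(
            [dataclasses.asdict(r) for r in results]
        )

    wil = summary["wilcoxon"]
    parts.append("## Degree comparisons (illicit vs full network)\n")
    parts.append(
        f"- drug degree: p = {wil['drug_degree']['p']:.2g} ({wil['drug_degree']['method']})"
    )
    parts.append(
        f"- gene degree: p = {wil['gene_degree']['p']:.2g} ({wil['gene_degree']['method']})"
    )
    parts.append("")
    if "candidate_overlap" in summary:
        ov = summary["candidate_overlap"]
        parts.append("## Candidate-gene overlap\n")
        parts.append(
            f"- {ov['observed']} of {ov['successes']} candidates fall in the "
            f"{ov['draws']}-gene network (universe {ov['population']}); "
            f"hypergeometric tail p = {ov['p']:.2g}, point probability = {ov['p_point']:.2g}"
        )
        parts.append("")
    tables["markdown"] = "\n".join(parts)
    return tables
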