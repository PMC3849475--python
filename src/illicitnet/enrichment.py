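"""Category over-representation analyses for drug and gene sets.

Three analyses share the statistics kernel:

* **ATC second-sublevel enrichment** — for each therapeutic subgroup
  (the letter + two digits prefix of an ATC code, e.g. N05
  "psycholeptics"), a two-sided Fisher exact test compares how often
  two drug sets fall in the subgroup.  Only drugs carrying at least one
  ATC code enter the comparison; a drug counts at most once per
  subgroup regardless of how many of its codes map there.
* **Comparative gene-term enrichment** — the same Fisher comparison
  between two disjoint target-gene sets over GO Slim-style terms, at a
  raw p < alpha significance rule.
* **Two-stage pathway enrichment** — a within-set hypergeometric test
  of one gene set against a gene universe per pathway, Benjamini-
  Hochberg adjusted across pathways; pathways passing the adjusted
  cutoff can then be compared between sets with the Fisher route.

Gene universes are always explicit parameters: overlap handling between
gene sets differs between studies, so no universe is ever inferred.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

from .io import ATC_CODE_RE, DrugRecord
from .stats import (
    ContingencyTable2x2,
    HypergeomQuery,
    PValue,
    benjamini_hochberg,
    fisher_exact_two_sided,
    hypergeom_pmf,
    hypergeom_sf,
)

__all__ = [
    "CategoryMembership",
    "EnrichmentResult",
    "OverlapResult",
    "atc_second_level",
    "atc_memberships",
    "drugs_with_atc",
    "drug_category_table",
    "enrich_drug_categories",
    "enrich_gene_terms_comparative",
    "enrich_pathways_within_set",
    "candidate_overlap_test",
    "load_membership_table",
    "write_results_table",
]

_ATC_PREFIX_RE = re.compile(r"^[A-Z]\d{2}")


@dataclass(frozen=True)
class CategoryMembership:
    """One category (ATC subgroup, GO term, or pathway) and its members."""

    category_id: str
    label: str
    members: frozenset[str]


@dataclass(frozen=True)
class EnrichmentResult:
    """One category row of an enrichment table (Fisher or hypergeometric)."""

    category_id: str
    label: str
    count_a: int
    pct_a: float
    count_b: int
    pct_b: float
    p: float
    p_adj: float | None = None
    significant: bool = False


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric overlap of a candidate gene list with a network.

    ``p`` is the upper-tail probability P(X >= observed); ``p_point`` is
    the point probability P(X = observed), reported because published
    overlap figures are sometimes the density at the observed count
    rather than the tail (the two agree closely when the tail is
    dominated by its first term).
    """

    p: PValue
    p_point: PValue
    population: int
    successes: int
    draws: int
    observed: int


def atc_second_level(code: str) -> str:
    """Therapeutic-subgroup prefix (letter + 2 digits) of a full ATC code."""
    code = code.strip()
    if not ATC_CODE_RE.match(code):
        raise ValueError(f"malformed ATC code {code!r}")
    return code[:3]


def drugs_with_atc(records: Iterable[DrugRecord]) -> frozenset[str]:
    """Drugs carrying at least one ATC code (the annotated universe)."""
    return frozenset(r.drug_id for r in records if r.atc_codes)


def atc_memberships(records: Iterable[DrugRecord]) -> list[CategoryMembership]:
    """Second-sublevel ATC categories observed in a drug collection.

    A drug belongs to a category if *any* of its codes maps there, and
    contributes at most once per category.
    """
    members: dict[str, set[str]] = {}
    for rec in records:
        for code in rec.atc_codes:
            members.setdefault(atc_second_level(code), set()).add(rec.drug_id)
    return [
        CategoryMembership(cat, cat, frozenset(ids))
        for cat, ids in sorted(members.items())
    ]


def drug_category_table(
    set_a: frozenset[str] | set[str],
    set_b: frozenset[str] | set[str],
    category: CategoryMembership,
) -> ContingencyTable2x2:
    """2x2 membership table of one category against two entity sets.

    Callers must restrict both sets to annotated entities beforehand
    (for ATC analyses: drugs carrying at least one code); an empty set
    is an error since its margin would be void.
    """
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty (restrict to annotated entities first)")
    in_a = len(category.members & set(set_a))
    in_b = len(category.members & set(set_b))
    return ContingencyTable2x2(in_a, in_b, len(set_a) - in_a, len(set_b) - in_b)


def _comparative(
    set_a: frozenset[str] | set[str],
    set_b: frozenset[str] | set[str],
    memberships: Sequence[CategoryMembership],
    alpha: float,
) -> list[EnrichmentResult]:
    results = []
    for cat in memberships:
        table = drug_category_table(set_a, set_b, cat)
        if table.n_in_a + table.n_in_b == 0:
            continue
        p = fisher_exact_two_sided(table)
        results.append(
            EnrichmentResult(
                category_id=cat.category_id,
                label=cat.label,
                count_a=table.n_in_a,
                pct_a=100.0 * table.n_in_a / len(set_a),
                count_b=table.n_in_b,
                pct_b=100.0 * table.n_in_b / len(set_b),
                p=p,
                significant=p < alpha,
            )
        )
    return sorted(results, key=lambda r: (r.p, r.category_id))


def enrich_drug_categories(
    set_a: frozenset[str] | set[str],
    set_b: frozenset[str] | set[str],
    memberships: Sequence[CategoryMembership],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Fisher over-representation of each drug category in set A vs set B.

    Emits one result per category with at least one member in A or B,
    sorted by ascending p; significance is raw p < alpha.
    """
    return _comparative(set_a, set_b, memberships, alpha)


def enrich_gene_terms_comparative(
    genes_a: frozenset[str] | set[str],
    genes_b: frozenset[str] | set[str],
    term_memberships: Sequence[CategoryMembership],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Comparative Fisher enrichment of terms between two gene sets."""
    return _comparative(genes_a, genes_b, term_memberships, alpha)


def enrich_pathways_within_set(
    genes: frozenset[str] | set[str],
    pathway_memberships: Sequence[CategoryMembership],
    universe: frozenset[str] | set[str],
    alpha_adj: float = 0.05,
) -> list[EnrichmentResult]:
    """Within-set hypergeometric pathway enrichment with BH adjustment.

    For each pathway the draw is the gene set of interest out of the
    declared universe; pathways without members in the universe are
    skipped.  ``significant`` marks rows with BH-adjusted p < alpha_adj.
    """
    genes = set(genes)
    universe = set(universe)
    if not genes <= universe:
        raise ValueError("gene set must be contained in the universe")
    rows = []
    for cat in pathway_memberships:
        in_universe = cat.members & universe
        if not in_universe:
            continue
        overlap = len(in_universe & genes)
        p = hypergeom_sf(
            HypergeomQuery(
                population=len(universe),
                successes=len(in_universe),
                draws=len(genes),
                observed=overlap,
            )
        )
        rows.append((cat, overlap, len(in_universe), p))
    adjusted = benjamini_hochberg([p for *_, p in rows])
    results = [
        EnrichmentResult(
            category_id=cat.category_id,
            label=cat.label,
            count_a=overlap,
            pct_a=100.0 * overlap / len(genes) if genes else 0.0,
            count_b=n_in_universe,
            pct_b=100.0 * n_in_universe / len(universe),
            p=p,
            p_adj=p_adj,
            significant=p_adj < alpha_adj,
        )
        for (cat, overlap, n_in_universe, p), p_adj in zip(rows, adjusted)
    ]
    return sorted(results, key=lambda r: (r.p_adj, r.p, r.category_id))


def candidate_overlap_test(
    candidate_genes: Iterable[str],
    network_genes: Iterable[str],
    universe_genes: Iterable[str],
) -> OverlapResult:
    """Hypergeometric enrichment of an external candidate list in a network.

    The population is the gene universe, successes are the candidates
    present in the universe, the draw is the network's gene set, and the
    observation is the candidate/network intersection.
    """
    universe = set(universe_genes)
    if not universe:
        raise ValueError("gene universe must be non-empty")
    network = set(network_genes)
    if not network <= universe:
        raise ValueError("network genes must be contained in the universe")
    candidates = set(candidate_genes) & universe
    observed = len(candidates & network)
    query = HypergeomQuery(
        population=len(universe),
        successes=len(candidates),
        draws=len(network),
        observed=observed,
    )
    return OverlapResult(
        p=hypergeom_sf(query),
        p_point=hypergeom_pmf(query),
        population=query.population,
        successes=query.successes,
        draws=query.draws,
        observed=observed,
    )


def load_membership_table(source: str | Path | IO) -> list[CategoryMembership]:
    """Read a long-format membership TSV: category_id, label, member_id."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"category_id", "label", "member_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"membership table must have columns {sorted(required)}")
    out = []
    for (cat, label), grp in df.groupby(["category_id", "label"], sort=True):
        out.append(CategoryMembership(cat, label, frozenset(grp["member_id"])))
    return out


def write_results_table(results: Sequence[EnrichmentResult], target: str | Path | IO) -> None:
    """Write enrichment results as a TSV mirroring the report-table columns."""
    df = pd.DataFrame(
        [
            (r.category_id, r.label, r.count_a, r.pct_a, r.count_b, r.pct_b, r.p, r.p_adj, r.significant)
            for r in results
        ],
        columns=["category_id", "label", "count_a", "pct_a", "count_b", "pct_b", "p", "p_adj", "significant"],
    )
    df.to_csv(target, sep="\t", index=False)
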