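# Methods

This note records the models, conventions and design choices behind
`illicitnet`, in the order the pipeline applies them, together with the
generator's assumptions and the limits of what the tests demonstrate.

## Records and mapping

A drug record carries an accession (`DB` + digits), a name, lower-cased
legal-status groups, free-text categories, full seven-character ATC
codes (letter, two digits, two letters, two digits), and protein-target
references with UniProtKB accessions and a species tag.  Only targets
whose species equals "Humans" (case-insensitive) pass into the analysis.
Gene identity is the mapped gene symbol: two accessions mapping to one
symbol become a single gene node, and repeated drug–gene actions
collapse to one unweighted edge.  Targets whose accession is absent
from the mapping table are dropped from networks but tallied in a
`MappingReport`, so attrition between "drugs in the file" and "drugs in
the network" is always auditable rather than silent.

## Networks

* **Illicit network** — drugs with the `illicit` group tag that have
  ≥ 1 mapped human target, plus their target genes.
* **Illicit-related drugs** — non-illicit drugs sharing ≥ 1 mapped
  target gene with ≥ 1 illicit drug.
* **Illicit-extended network** — illicit ∪ related drugs; its gene set
  is exactly the illicit target genes, and edges of related drugs are
  restricted to that gene set.  Two invariants are asserted on every
  build: the illicit network is an edge-subset of the extended one, and
  no extended edge touches a gene outside the illicit target set.
* **Full network** — all target-bearing drugs and their genes.

The drug partition (illicit / illicit-related / other) is pairwise
disjoint and exhaustive over target-bearing drugs; drugs without
mappable targets are reported in a separate `excluded` set.

## Centrality and cutoffs

Degree is the incident-edge count.  Betweenness is computed on the
undirected bipartite graph, unnormalized, over **unordered** node pairs
— each pair {s, t} counted once, disconnected pairs contributing zero.
Some network tools count ordered pairs, which exactly doubles every
value; `pair_convention="ordered"` provides that scale for parity
checks and the convention in force is recorded in run metadata.  The
unordered convention is the default because a fixed cutoff such as
"betweenness > 2000" is only meaningful once the scale is pinned down.

Hub and bridge flags use *strict* exceedance (`metric > threshold`).
Thresholds come from either:

* **manual** — an explicit value, the reproducible way to apply a
  published cutoff (e.g. degree > 8); or
* **knee** — rank the values in descending order, rescale rank and
  value to the unit square, and take the value at maximum perpendicular
  distance from the chord joining the curve's endpoints.  Ties break
  toward the smallest rank; a maximum distance below 0.01 flags the
  decision `low_confidence` (a near-linear curve has no meaningful
  knee); fewer than three distinct values is an error directing the
  caller to manual mode.  The knee is a formalization of the common
  visual "where the distribution reaches its asymptote" judgment, which
  is not itself an algorithm — hence the first-class manual override.

Degree comparisons between networks use a two-sided Wilcoxon rank-sum
test: exhaustive enumeration over all relabelings when both samples
have ≤ 10 observations (midranks make identical samples give p = 1
exactly), otherwise the normal approximation with tie and continuity
corrections.  Whether the illicit drugs are excluded from the
full-network sample is an explicit flag (`wilcoxon_exclude_illicit`,
default off — the comparison is illicit vs *all* drugs).

## Statistics kernel

All tail sums are accumulated in log space from log-gamma binomial
coefficients, so p-values of order 1e-26 carry full relative precision.
A p-value is never reported as zero: if even the log-space result
underflows the double range, the smallest positive double is returned
and flagged on the `PValue` object (which otherwise behaves as a plain
float and keeps its exact natural log in `log_p`).

* **Fisher exact, two-sided** — the minimum-likelihood convention: sum
  the hypergeometric point probabilities of all tables with the
  observed margins whose probability is ≤ the observed table's, with a
  1e-7 relative guard against floating-point ties (the convention used
  by the common R implementation, whose `< 2.2e-16` floor appears in
  published tables).  A table with an empty row or column carries no
  information and returns p = 1 with a warning.  One-sided alternatives
  exist for sensitivity checks.
* **Hypergeometric tail** — exact log-space sum of `P(X ≥ k)`;
  `P(X ≥ support minimum) = 1` identically.
* **Benjamini–Hochberg** — standard step-up with enforced monotonicity,
  clipped at 1, output in input order.

### Tail versus point probability in overlap tests

`candidate_overlap_test` returns the upper-tail `P(X ≥ k)` as its
p-value — the correct enrichment test — and additionally exposes the
point probability `P(X = k)`.  The reason: published overlap figures
are sometimes the hypergeometric *density* at the observed count (the
value returned by, e.g., R's `dhyper`) rather than the tail.  At the
published scale used in the acceptance suite (universe 1333, 47
candidate successes, 73 draws, 17 observed) the tail is 4.2e-11 while
the point probability is 3.9e-11; the two nearly coincide because the
tail is dominated by its first term, but they differ at two significant
figures, so both are reported and the distinction is kept explicit.

## Enrichment analyses

* **ATC second sublevel** — the therapeutic-subgroup tier (letter + two
  digits, e.g. N05 "psycholeptics").  A drug belongs to a subgroup if
  *any* of its codes maps there, contributing at most once; drugs
  without any ATC code are excluded from both comparison sets before
  counting, so percentages are on annotated drugs only.  Categories are
  compared between drug sets with the two-sided Fisher test at raw
  p < 0.05.
* **Comparative gene terms** — the same Fisher route between two
  disjoint target-gene sets (illicit vs non-illicit), raw p < 0.05.
* **Two-stage pathways** — stage one tests one gene set against a gene
  universe per pathway (hypergeometric tail) with BH adjustment at 0.05;
  stage two compares sets with the Fisher route at raw 0.05.
* **Gene universes are explicit parameters everywhere.**  Whether
  "non-illicit target genes" excludes the genes also hit by illicit
  drugs changes the universe sizes, and published accounts do not
  always pin this down; the package therefore never infers a universe.

## Synthetic data generator

The generator emulates the qualitative structure of a curated
drug-database slice, not its content:

* **Clusters.**  Four therapeutic clusters by default — depressants,
  stimulants, analgesics, steroids — of 20 drugs × 15 genes each.
  Within-cluster drug–gene edges are Bernoulli with `p_within = 0.3`;
  cross-cluster edges with `p_between = 0.01`.  This is a bipartite
  planted-partition model: the simplest generative model that yields
  tight, identifiable clusters.  It is *not* degree-corrected; the
  heavy tail comes from designated hub drugs (one per cluster) whose
  edge probability is multiplied by `hub_boost = 3` (capped at 1).
* **Bridge genes.**  Three planted genes chain the clusters
  (depressants–stimulants–analgesics–steroids).  A bridge gene attaches
  to each of its two clusters at the hub-grade rate
  `min(1, p_within · hub_boost)`, with at least two edges per side
  guaranteed.  The hub-grade attachment is deliberate: in real
  drug–target data the genes that link therapeutic clusters are
  themselves highly targeted (estrogen receptor between analgesics and
  steroids, GABA-A subunits between depressants and stimulants), and a
  weakly attached gene is simply not a bridge — early prototypes with
  2–6 edges per side produced "planted" bridges that did not dominate
  betweenness, i.e. a ground-truth label that was false.
* **Illicit flags.**  Drawn per cluster: 0.75 for depressants, 0.15
  elsewhere — a five-fold concentration mirroring the predominance of
  sedative/hypnotic compounds among illicit drugs, while keeping the
  illicit group a minority (~30%) of the collection.
* **ATC codes.**  85% of drugs carry 1–2 syntactically valid codes
  whose second sublevel is drawn from the cluster's pool (dominant code
  weight ≥ 0.7, pools disjoint across clusters; suffixes are arbitrary,
  since only the second sublevel is analyzed).  Each cluster therefore
  plants one (cluster → dominant code) enrichment, recorded in the
  ground truth; with disjoint pools this association is recoverable at
  p ≪ 1e-3 in every seed.  The dominant-code weights were set by a
  design-time power analysis so that the planted association is
  unambiguous at the default cluster size — a weakly planted enrichment
  at n = 20 drugs per cluster is statistically invisible in a
  non-negligible fraction of seeds.
* **Determinism.**  One `numpy` generator seeded from the config drives
  all draws in a fixed order; identical configs produce byte-identical
  XML, and the pipeline writes sorted, canonically formatted outputs so
  a whole run is byte-reproducible.

What passing tests on this generator do **not** show: robustness to
degree-correlated noise, to partial target annotation, to multi-species
ambiguity beyond the Humans filter, or to the scale of a real database
(thousands of drugs, power-law degrees).  The synthetic default also
has an empty "other drugs" set — every cluster contains illicit drugs,
so all non-illicit drugs end up illicit-related; analyses comparing
against "other" drugs are exercised with constructed count fixtures
instead.

## Study sizes and numerics

The recovery study uses 20 generator replicates (hub recovery = all
planted hubs flagged by the knee rule on the full network; bridge
recovery = planted bridges are exactly the top-k betweenness nodes),
and the null calibration uses 500 balanced 200-vs-200 category draws at
membership probability 0.3 — sizes at which the binomial noise of the
measured rates is well inside the acceptance bands.  Betweenness is
validated against an exact-rational brute-force geodesic oracle on
graphs of ≤ 12 nodes; Fisher and hypergeometric values against
full-support enumeration oracles with `fractions.Fraction` arithmetic
up to population 200.  Percentages and mean degrees are rounded
half-up at one decimal in reports; summaries keep the unrounded value
alongside, because published one-decimal figures occasionally disagree
with the underlying ratio (e.g. a printed mean of 6.6 where the
edge/node ratio gives 563/86 = 6.55, which rounds to 6.5) — the report
shows both rather than hiding the discrepancy.

## Known limitations

* Interactions are unweighted and unsigned; agonist/antagonist
  direction, affinities, and drug–drug or protein–protein edges are out
  of scope.
* The knee detector assumes a convex, monotone rank curve; on
  multi-elbow or near-linear curves it returns a flagged low-confidence
  decision and a manual threshold should be preferred.
* Betweenness on large full networks is the most expensive step
  (all-pairs shortest paths); the pipeline skips it for the full
  network unless requested.
* Real-data censuses (node and edge counts of a specific database
  release) depend on licensed content this package does not ship; the
  acceptance suite therefore validates statistics recomputable from
  printed counts, arithmetic identities, and planted-structure
  recovery, not database snapshots.
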