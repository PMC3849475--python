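"""Degree, betweenness, cutoff detection, and hub/bridge flagging.

Betweenness centrality of a node v is the sum over unordered node pairs
{s, t} (s != t != v) of the fraction of shortest s-t paths passing
through v.  Values are reported unnormalized (raw path-pair counts), the
scale on which a manual cutoff such as "betweenness > 2000" operates.
Some network tools count ordered pairs instead, exactly doubling every
value; that convention is available via ``pair_convention="ordered"``
and is recorded in the output metadata, never silently applied.

Hubs and bridge nodes are defined by a *strict* threshold exceedance on
degree and betweenness respectively.  The threshold can be supplied
manually (the documented way to reproduce published cutoffs) or detected
from the ranked distribution with a Kneedle-style knee finder: the rank
curve is normalized to the unit square and the point of maximum
perpendicular distance from the chord joining its endpoints is taken as
the knee.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .network import BipartiteNetwork
from .stats import RankSumResult, rank_sum_test

__all__ = [
    "CentralityRecord",
    "CutoffDecision",
    "degree",
    "betweenness",
    "detect_cutoff",
    "flag_hubs",
    "flag_bridges",
    "compare_degree_distributions",
    "centrality_records",
]


@dataclass(frozen=True)
class CentralityRecord:
    """Per-node centrality summary with hub/bridge flags."""

    node_id: str
    node_kind: str  # "drug" or "gene"
    degree: int
    betweenness: float
    is_hub: bool
    is_bridge: bool


@dataclass(frozen=True)
class CutoffDecision:
    """A threshold on a centrality metric and how it was chosen.

    ``curve`` is the ranked distribution (rank, value) in descending
    value order; for the knee method ``knee_rank`` marks the chosen
    point and ``low_confidence`` flags near-linear curves on which the
    knee is not meaningful.
    """

    metric: str  # "degree" or "betweenness"
    threshold: float
    method: str  # "knee" or "manual"
    curve: tuple[tuple[int, float], ...]
    knee_rank: int | None = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.method == "knee" and self.curve:
            if self.threshold < min(v for _, v in self.curve):
                raise ValueError("knee threshold below the minimum observed value")


def degree(net: BipartiteNetwork) -> dict[str, int]:
    """Incident edge count per node; sums to |edges| on each side."""
    deg = {n: 0 for n in net.drug_nodes | net.gene_nodes}
    for d, g in net.edges:
        deg[d] += 1
        deg[g] += 1
    return deg


def betweenness(
    net: BipartiteNetwork | nx.Graph, pair_convention: str = "unordered"
) -> dict[str, float]:
    """Unnormalized betweenness centrality of every node.

    Shortest paths are taken in the undirected bipartite graph;
    disconnected pairs contribute nothing.  With the default unordered
    convention each pair {s, t} is counted once; ``"ordered"`` doubles
    every value (both (s,t) and (t,s)) for parity with tools that count
    directed pairs.
    """
    g = net.to_networkx() if isinstance(net, BipartiteNetwork) else net
    values = nx.betweenness_centrality(g, normalized=False)
    if pair_convention == "ordered":
        values = {n: 2.0 * v for n, v in values.items()}
    elif pair_convention != "unordered":
        raise ValueError(f"unknown pair convention {pair_convention!r}")
    return values


def detect_cutoff(
    values: Iterable[float],
    metric: str = "degree",
    method: str = "knee",
    manual_threshold: float | None = None,
) -> CutoffDecision:
    """Choose a hub/bridge threshold from a metric distribution.

    ``method="manual"`` echoes ``manual_threshold`` (the reproducible way
    to apply a published cutoff).  ``method="knee"`` ranks the values in
    descending order, rescales rank and value to [0, 1], and returns the
    value at maximum perpendicular distance from the chord joining the
    first and last point; ties break toward the smallest rank.  At least
    three distinct values are required, otherwise the caller is told to
    use manual mode.
    """
    vals = sorted((float(v) for v in values), reverse=True)
    curve = tuple((rank, v) for rank, v in enumerate(vals, start=1))

    if method == "manual":
        if manual_threshold is None:
            raise ValueError("manual method requires manual_threshold")
        return CutoffDecision(metric=metric, threshold=float(manual_threshold), method="manual", curve=curve)
    if method != "knee":
        raise ValueError(f"unknown cutoff method {method!r}")

    if len(set(vals)) < 3:
        raise ValueError(
            "knee detection needs at least 3 distinct values; "
            "use method='manual' with an explicit threshold"
        )

    n = len(vals)
    x = np.arange(n) / (n - 1)
    vmax, vmin = vals[0], vals[-1]
    y = (np.asarray(vals) - vmin) / (vmax - vmin)
    # perpendicular distance from the chord y = 1 - x (unit-square endpoints)
    dist = np.abs(x + y - 1.0) / math.sqrt(2.0)
    knee_idx = int(np.argmax(dist))  # argmax keeps the first (smallest-rank) tie
    low_confidence = float(dist[knee_idx]) < 0.01
    return CutoffDecision(
        metric=metric,
        threshold=vals[knee_idx],
        method="knee",
        curve=curve,
        knee_rank=knee_idx + 1,
        low_confidence=low_confidence,
    )


def _exceeding(values: Mapping[str, float], threshold: float) -> frozenset[str]:
    return frozenset(n for n, v in values.items() if v > threshold)


def flag_hubs(net: BipartiteNetwork, cutoff: CutoffDecision | float) -> frozenset[str]:
    """Nodes with degree strictly above the cutoff."""
    threshold = cutoff.threshold if isinstance(cutoff, CutoffDecision) else float(cutoff)
    return _exceeding(degree(net), threshold)


def flag_bridges(
    net: BipartiteNetwork,
    cutoff: CutoffDecision | float,
    pair_convention: str = "unordered",
    precomputed: Mapping[str, float] | None = None,
) -> frozenset[str]:
    """Nodes with betweenness strictly above the cutoff."""
    threshold = cutoff.threshold if isinstance(cutoff, CutoffDecision) else float(cutoff)
    values = precomputed if precomputed is not None else betweenness(net, pair_convention)
    return _exceeding(values, threshold)


def compare_degree_distributions(sample_a: Sequence[float], sample_b: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum comparison of two degree samples."""
    return rank_sum_test(sample_a, sample_b)


def centrality_records(
    net: BipartiteNetwork,
    degree_cutoff: CutoffDecision | float,
    betweenness_cutoff: CutoffDecision | float,
    pair_convention: str = "unordered",
) -> list[CentralityRecord]:
    """Full per-node centrality table with hub and bridge flags."""
    deg = degree(net)
    btw = betweenness(net, pair_convention)
    hubs = flag_hubs(net, degree_cutoff)
    bridges = flag_bridges(net, betweenness_cutoff, precomputed=btw)
    records = []
    for node in sorted(net.drug_nodes) + sorted(net.gene_nodes):
        records.append(
            CentralityRecord(
                node_id=node,
                node_kind="drug" if node in net.drug_nodes else "gene",
                degree=deg[node],
                betweenness=btw[node],
                is_hub=node in hubs,
                is_bridge=node in bridges,
            )
        )
    return records
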