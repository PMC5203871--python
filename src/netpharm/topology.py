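"""Topological indices and the above-average main-node (hub) rule.

Every node is scored by three indices — degree, shortest-path
betweenness and closeness — and a node whose three indices are all at
or above the network-wide arithmetic means is a *main node*.

Conventions (chosen for a possibly disconnected, unweighted, undirected
PPI network):

* betweenness is Brandes shortest-path betweenness with fractional
  credit over equally short paths, endpoints excluded, normalized by
  (N-1)(N-2)/2 so values lie in [0, 1];
* closeness is the component-scaled (Wasserman–Faust) form
  ((n_v-1)/(N-1)) * ((n_v-1)/sum of distances within the component),
  0 for isolated nodes.
"""

from __future__ import annotations

import math
from statistics import fmean
from typing import Iterable, Sequence

import networkx as nx

from .model import CentralityRecord, MainNodeThresholds, TypedNetwork, ValidationError

__all__ = [
    "degree",
    "betweenness",
    "closeness",
    "centrality_records",
    "select_main_nodes",
    "analyze",
]


def degree(net: TypedNetwork) -> dict[str, int]:
    """Incident-edge count per node."""
    return {n: d for n, d in net.graph.degree()}


def betweenness(net: TypedNetwork) -> dict[str, float]:
    """Pair-normalized shortest-path betweenness (endpoints excluded)."""
    return nx.betweenness_centrality(net.graph, normalized=True)


def closeness(net: TypedNetwork) -> dict[str, float]:
    """Component-scaled closeness; 0 for isolated nodes."""
    return nx.closeness_centrality(net.graph, wf_improved=True)


def centrality_records(net: TypedNetwork) -> list[CentralityRecord]:
    """All three indices for every node of the network (is_main unset)."""
    deg = degree(net)
    btw = betweenness(net)
    clo = closeness(net)
    return [
        CentralityRecord(
            node=n,
            role=net.role_of(n),
            degree=deg[n],
            betweenness=btw[n],
            closeness=clo[n],
        )
        for n in sorted(net.graph.nodes)
    ]


def select_main_nodes(
    records: Sequence[CentralityRecord],
) -> tuple[MainNodeThresholds, set[str]]:
    """Apply the above-average rule over one network's records.

    Thresholds are the arithmetic means of each index over *all* nodes
    (isolates included); a node is selected when degree, betweenness and
    closeness are each >= the corresponding mean (inclusive).
    """
    if not records:
        raise ValidationError("no centrality records to select from")
    thresholds = MainNodeThresholds(
        mean_degree=fmean(r.degree for r in records),
        mean_betweenness=fmean(r.betweenness for r in records),
        mean_closeness=fmean(r.closeness for r in records),
    )
    def at_least(value: float, mean: float) -> bool:
        # inclusive >= with float slack so a regular graph (every index
        # equal to its mean up to round-off) selects all nodes
        return value >= mean or math.isclose(value, mean, rel_tol=1e-9, abs_tol=1e-12)

    selected = {
        r.node
        for r in records
        if at_least(r.degree, thresholds.mean_degree)
        and at_least(r.betweenness, thresholds.mean_betweenness)
        and at_least(r.closeness, thresholds.mean_closeness)
    }
    return thresholds, selected


def analyze(
    net: TypedNetwork,
) -> tuple[list[CentralityRecord], MainNodeThresholds, set[str]]:
    """Compute records, thresholds and the main-node set in one pass."""
    records = centrality_records(net)
    thresholds, selected = select_main_nodes(records)
    flagged = [
        CentralityRecord(
            node=r.node,
            role=r.role,
            degree=r.degree,
            betweenness=r.betweenness,
            closeness=r.closeness,
            is_main=r.node in selected,
        )
        for r in records
    ]
    return flagged, thresholds, selected
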