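"""Builders for the four typed networks and the hub-interaction subnetwork.

The pipeline relates the formula to the disease through four views:

1. herb -> compound -> pharmacology -> traditional effect;
2. the bipartite compound -> predicted-target map;
3. herb -> target, with compounds contracted out and disease targets
   attached through their protein-protein interactions with the
   predicted targets;
4. the full PPI neighbourhood of predicted + disease targets.

A fifth builder induces the direct-interaction subnetwork of a
main-node (hub) set.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

from .model import (
    CompoundTargetTable,
    DiseaseTargetSet,
    HerbCompoundTable,
    PharmEfficacyTable,
    ScoredInteraction,
    TypedNetwork,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "assign_roles",
    "build_pharm_efficacy_network",
    "build_compound_target_network",
    "build_herb_target_disease_network",
    "build_ppi_network",
    "main_node_subnetwork",
]


def assign_roles(
    compound_targets: Iterable[str], disease: DiseaseTargetSet
) -> dict[str, str]:
    """Partition target symbols into compound / infertility / shared roles.

    A symbol in both the compound-target set and the disease list is a
    shared target; each symbol receives exactly one role.
    """
    ct = {t.upper() for t in compound_targets}
    roles: dict[str, str] = {}
    for t in ct:
        roles[t] = "shared_target" if t in disease else "compound_target"
    for t in disease:
        roles.setdefault(t, "infertility_target")
    return roles


def build_pharm_efficacy_network(
    tbl: PharmEfficacyTable, herbs: HerbCompoundTable
) -> TypedNetwork:
    """Herb–compound–pharmacology–effect network (formula rationale view).

    Mirrors the curated table exactly: herb–compound edges from the
    membership table, compound–pharmacology and pharmacology–effect
    edges from the pharmacology rows.  Compounds without pharmacology
    keep their herb edges only.
    """
    orphans = tbl.compounds - herbs.compounds
    if orphans:
        raise ValidationError(
            f"compound(s) {sorted(orphans)} have pharmacology but no herb"
        )
    net = TypedNetwork(name="pharm_efficacy")
    for herb, compound in herbs.rows:
        net.add_node(herb, "herb")
        net.add_node(compound, "compound")
        net.add_edge(herb, compound, relation="contains")
    for row in tbl.rows:
        net.add_node(row.pharmacology_statement, "pharmacology")
        net.add_node(row.traditional_effect, "effect")
        net.add_edge(row.compound_id, row.pharmacology_statement, relation="exhibits")
        net.add_edge(
            row.pharmacology_statement, row.traditional_effect, relation="supports"
        )
    return net


def build_compound_target_network(ct: CompoundTargetTable) -> TypedNetwork:
    """Bipartite compound–target network: one node per compound and per
    target, one edge per distinct (compound, target) pair."""
    net = TypedNetwork(name="compound_target")
    for compound, target in ct.rows:
        net.add_node(compound, "compound")
        net.add_node(target, "compound_target")
        net.add_edge(compound, target, relation="targets")
    return net


def build_herb_target_disease_network(
    herbs: HerbCompoundTable,
    ct: CompoundTargetTable,
    disease: DiseaseTargetSet,
    ppi: Optional[Sequence[ScoredInteraction]] = None,
) -> TypedNetwork:
    """Herb–target–disease network with compounds contracted out.

    Each herb connects directly to the union of its compounds' targets
    ("herb relation" edges).  Disease targets enter in two ways: those
    also hit by a compound become shared targets through the herb edges;
    the rest are attached through their (pre-filtered) PPI edges with
    compound/shared targets ("target relation" edges) and a pure disease
    target with no such interaction is dropped from this view — it has
    nothing to connect it.  Dropped symbols are logged.
    """
    if not herbs.rows:
        raise ValidationError("herb/compound table is empty")
    roles = assign_roles(ct.targets, disease)
    net = TypedNetwork(name="herb_target_disease")
    for herb in sorted(herbs.herbs):
        net.add_node(herb, "herb")
    for target in sorted(ct.targets):
        net.add_node(target, roles[target])
    for herb in sorted(herbs.herbs):
        herb_targets: set[str] = set()
        for compound in herbs.compounds_of(herb):
            herb_targets |= ct.targets_of(compound)
        for target in sorted(herb_targets):
            net.add_edge(herb, target, relation="herb")

    pure_disease = disease.targets - ct.targets
    attached: set[str] = set()
    if ppi:
        for it in ppi:
            a, b = it.pair
            # black edge: disease-side endpoint interacting with a
            # compound/shared target (disease-disease pairs are not a
            # relation this view draws)
            black = (a in disease.targets and b in ct.targets) or (
                b in disease.targets and a in ct.targets
            )
            if not black:
                continue
            for end in (a, b):
                if end in pure_disease and end not in net:
                    net.add_node(end, "infertility_target")
                    attached.add(end)
            net.add_edge(a, b, relation="target")
    dropped = sorted(pure_disease - attached)
    if dropped:
        logger.info(
            "herb_target_disease: dropped %d disease target(s) with no "
            "PPI support among targets: %s",
            len(dropped),
            dropped,
        )
    return net


def build_ppi_network(
    ct: CompoundTargetTable,
    disease: DiseaseTargetSet,
    ppi: Sequence[ScoredInteraction],
) -> TypedNetwork:
    """Seed-neighbourhood PPI network.

    Node set = seeds (compound targets ∪ disease targets) plus every
    direct PPI partner of a seed; edge set = all given interactions with
    both endpoints in that node set (so partner–partner edges are kept).
    Interactions are expected to be confidence-filtered already.
    """
    seeds = ct.targets | disease.targets
    roles = assign_roles(ct.targets, disease)
    partners: set[str] = set()
    for it in ppi:
        a, b = it.pair
        if a in seeds and b not in seeds:
            partners.add(b)
        elif b in seeds and a not in seeds:
            partners.add(a)
    net = TypedNetwork(name="ppi")
    for node in sorted(seeds):
        net.add_node(node, roles[node])
    for node in sorted(partners):
        net.add_node(node, "other_protein")
    keep = seeds | partners
    for it in ppi:
        a, b = it.pair
        if a in keep and b in keep:
            net.add_edge(a, b, relation="pp")
    return net


def main_node_subnetwork(net: TypedNetwork, main: Iterable[str]) -> TypedNetwork:
    """Direct-interaction subnetwork of a main-node set.

    Induces the subgraph on the main nodes and then removes isolates:
    only main nodes with at least one direct interaction to another main
    node remain.
    """
    main = set(main)
    missing = main - set(net.nodes())
    if missing:
        raise ValidationError(f"main node(s) not in network: {sorted(missing)[:5]}")
    sub = TypedNetwork(name=f"{net.name}_main_subnetwork" if net.name else "main_subnetwork")
    g = net.graph
    kept = [
        n for n in sorted(main) if any(nb in main for nb in g.neighbors(n))
    ]
    for node in kept:
        sub.add_node(node, net.role_of(node))
    for u, v, data in g.edges(data=True):
        if u in main and v in main:
            sub.add_edge(u, v, data.get("relation"))
    return sub
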