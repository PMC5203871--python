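from __future__ import annotations

import itertools
import random

import networkx as nx
import pytest

from netpharm import networks as nets
from netpharm import synthetic
from netpharm.model import (
    CompoundTargetTable,
    DiseaseTargetSet,
    HerbCompoundTable,
    PharmEfficacyRow,
    PharmEfficacyTable,
    ScoredInteraction,
    TypedNetwork,
    ValidationError,
)


class TestRoleAssignment:
    def test_partition_is_exclusive_and_exhaustive(self):
        roles = nets.assign_roles(
            {"A", "B", "S"}, DiseaseTargetSet({"S", "D1", "D2"})
        )
        assert roles == {
            "A": "compound_target",
            "B": "compound_target",
            "S": "shared_target",
            "D1": "infertility_target",
            "D2": "infertility_target",
        }


class TestPharmEfficacyNetwork:
    def test_pachyman_reaches_spleen_through_sod(self, study_tables):
        net = nets.build_pharm_efficacy_network(
            study_tables["pharm"], study_tables["herbs"]
        )
        g = net.graph
        assert g.has_edge("pachyman", "Increasing SOD activity")
        assert g.has_edge("Increasing SOD activity", "spleen_invigorating")

    def test_compound_without_pharmacology_keeps_herb_edges_only(self, study_tables):
        net = nets.build_pharm_efficacy_network(
            study_tables["pharm"], study_tables["herbs"]
        )
        assert net.role_of("pachymic_acid") == "compound"
        assert net.graph.degree("pachymic_acid") == len(
            study_tables["herbs"].herbs_of("pachymic_acid")
        )

    def test_empty_table_leaves_herbs_and_compounds(self):
        herbs = HerbCompoundTable([("h1", "c1"), ("h2", "c2")])
        net = nets.build_pharm_efficacy_network(PharmEfficacyTable(()), herbs)
        assert set(net.role_census()) == {"herb", "compound"}
        assert net.number_of_nodes() == 4

    def test_orphan_compound_rejected(self):
        herbs = HerbCompoundTable([("h1", "c1")])
        tbl = PharmEfficacyTable(
            [PharmEfficacyRow("ghost", "Reducing LPO", "qi_dispersing")]
        )
        with pytest.raises(ValidationError, match="ghost"):
            nets.build_pharm_efficacy_network(tbl, herbs)


class TestCompoundTargetNetwork:
    def test_single_pair(self):
        net = nets.build_compound_target_network(CompoundTargetTable([("c1", "t1")]))
        assert net.number_of_nodes() == 2
        assert net.number_of_edges() == 1

    def test_counts_equal_closed_form_over_generated_inputs(self):
        for seed in range(5):
            cfg = synthetic.GeneratorConfig(
                seed=seed, n_compounds=7, n_targets=50, promiscuous_target_count=2,
                n_shared_targets=0, n_disease_targets=0,
            )
            ct = synthetic.generate_compound_targets(cfg)
            net = nets.build_compound_target_network(ct)
            assert net.number_of_nodes() == len(ct.compounds) + len(ct.targets)
            assert net.number_of_edges() == len(ct.rows)

    def test_promiscuous_target_degree_equals_compound_count(self, study_tables):
        net = nets.build_compound_target_network(study_tables["ct"])
        assert net.graph.degree("AR") == 11


class TestHerbTargetDiseaseNetwork:
    def test_tiny_contraction_to_two_node_path(self):
        herbs = HerbCompoundTable([("h1", "c1")])
        ct = CompoundTargetTable([("c1", "T1")])
        disease = DiseaseTargetSet({"D1"})
        net = nets.build_herb_target_disease_network(herbs, ct, disease)
        assert sorted(net.nodes()) == ["T1", "h1"]
        assert net.number_of_edges() == 1

    def test_disease_subset_of_targets_is_all_shared(self):
        herbs = HerbCompoundTable([("h1", "c1"), ("h1", "c2")])
        ct = CompoundTargetTable([("c1", "T1"), ("c2", "T2")])
        disease = DiseaseTargetSet({"T1", "T2"})
        net = nets.build_herb_target_disease_network(herbs, ct, disease)
        census = net.role_census()
        assert census.get("infertility_target", 0) == 0
        assert census["shared_target"] == 2

    def test_black_edges_attach_supported_disease_targets(self):
        herbs = HerbCompoundTable([("h1", "c1")])
        ct = CompoundTargetTable([("c1", "T1"), ("c1", "T2")])
        disease = DiseaseTargetSet({"D1", "D2"})
        ppi = [ScoredInteraction("D1", "T1", 0.9)]
        net = nets.build_herb_target_disease_network(herbs, ct, disease, ppi)
        assert "D1" in net and net.role_of("D1") == "infertility_target"
        assert "D2" not in net  # no interaction with any compound target

    def test_herb_degree_of_target_counts_owning_herbs(self):
        herbs = HerbCompoundTable(
            [("h1", "c1"), ("h2", "c2"), ("h2", "c3"), ("h3", "c4")]
        )
        ct = CompoundTargetTable(
            [("c1", "T1"), ("c2", "T1"), ("c3", "T1"), ("c4", "T2")]
        )
        net = nets.build_herb_target_disease_network(
            herbs, ct, DiseaseTargetSet({"D9"})
        )
        # T1 hit via c1 (h1) and via c2+c3 (both h2): herb-degree 2
        assert net.graph.degree("T1") == 2
        assert net.graph.degree("T2") == 1

    def test_role_census_sums_to_node_count(self, study_tables):
        net = nets.build_herb_target_disease_network(
            study_tables["herbs"],
            study_tables["ct"],
            study_tables["disease"],
            study_tables["ppi"],
        )
        assert sum(net.role_census().values()) == net.number_of_nodes()


class TestPpiNetwork:
    def test_empty_ppi_keeps_seed_nodes_only(self):
        ct = CompoundTargetTable([("c1", "T1")])
        disease = DiseaseTargetSet({"D1"})
        net = nets.build_ppi_network(ct, disease, [])
        assert sorted(net.nodes()) == ["D1", "T1"]
        assert net.number_of_edges() == 0

    def test_partner_partner_edges_retained(self):
        ct = CompoundTargetTable([("c1", "T1")])
        disease = DiseaseTargetSet({"D1"})
        ppi = [
            ScoredInteraction("T1", "P1", 0.9),
            ScoredInteraction("T1", "P2", 0.9),
            ScoredInteraction("P1", "P2", 0.9),
        ]
        net = nets.build_ppi_network(ct, disease, ppi)
        assert net.graph.has_edge("P1", "P2")

    def test_matches_bruteforce_neighborhood_induction(self):
        rng = random.Random(42)
        names = [f"N{i}" for i in range(10)]
        for _ in range(25):
            seeds = set(rng.sample(names, 3))
            edges = set()
            while len(edges) < 12:
                a, b = rng.sample(names, 2)
                edges.add(tuple(sorted((a, b))))
            ppi = [ScoredInteraction(a, b, 0.9) for a, b in sorted(edges)]
            ct = CompoundTargetTable([("c1", t) for t in sorted(seeds)])
            disease = DiseaseTargetSet({sorted(seeds)[0]})
            net = nets.build_ppi_network(ct, disease, ppi)
            # oracle: seeds plus direct partners; edges fully inside
            keep = set(seeds)
            for a, b in edges:
                if a in seeds or b in seeds:
                    keep.update((a, b))
            kept_edges = {e for e in edges if e[0] in keep and e[1] in keep}
            assert set(net.nodes()) == keep
            assert set(map(tuple, net.edges())) == kept_edges


class TestMainNodeSubnetwork:
    def _net(self, edges, nodes):
        net = TypedNetwork("t")
        for n in nodes:
            net.add_node(n, "other_protein")
        for u, v in edges:
            net.add_edge(u, v)
        return net

    def test_adjacent_pair_survives(self):
        net = self._net([("A", "B")], ["A", "B", "C"])
        sub = nets.main_node_subnetwork(net, {"A", "B"})
        assert sorted(sub.nodes()) == ["A", "B"]
        assert sub.number_of_edges() == 1

    def test_non_adjacent_pair_vanishes(self):
        net = self._net([("A", "C"), ("B", "C")], ["A", "B", "C"])
        sub = nets.main_node_subnetwork(net, {"A", "B"})
        assert sub.number_of_nodes() == 0

    def test_unknown_main_node_rejected(self):
        net = self._net([], ["A"])
        with pytest.raises(ValidationError):
            nets.main_node_subnetwork(net, {"Z"})

    def test_equals_bruteforce_edge_filtering_on_small_graphs(self):
        rng = random.Random(7)
        for seed in range(60):
            g = nx.gnp_random_graph(rng.randint(2, 8), rng.choice([0.2, 0.4, 0.7]),
                                    seed=seed)
            nodes = [str(n) for n in g.nodes]
            net = self._net([(str(u), str(v)) for u, v in g.edges], nodes)
            main = set(rng.sample(nodes, rng.randint(0, len(nodes))))
            sub = nets.main_node_subnetwork(net, main)
            brute_edges = {
                tuple(sorted((str(u), str(v))))
                for u, v in g.edges
                if str(u) in main and str(v) in main
            }
            brute_nodes = {n for e in brute_edges for n in e}
            assert set(sub.nodes()) == brute_nodes
            assert set(map(tuple, sub.edges())) == brute_edges
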