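from __future__ import annotations

import random
from pathlib import Path

import networkx as nx
import pytest

from netpharm import io as npio
from netpharm import synthetic
from netpharm.model import DiseaseTargetSet, TypedNetwork


@pytest.fixture(scope="session")
def study_bundle(tmp_path_factory) -> synthetic.FixtureBundle:
    """One generated input bundle at the published cardinalities."""
    out = tmp_path_factory.mktemp("study_bundle")
    return synthetic.study_scale_fixture(seed=1, out_dir=out)


@pytest.fixture(scope="session")
def study_tables(study_bundle):
    """Loaded tables of the study-scale bundle (PPI already >0.4-filtered)."""
    return {
        "herbs": npio.read_herb_compound_table(study_bundle.herb_compounds),
        "ct": npio.read_compound_target_table(study_bundle.compound_targets),
        "disease": npio.read_disease_targets(study_bundle.disease_targets),
        "ppi": npio.read_scored_interactions(study_bundle.ppi_edges, min_score=0.4),
        "annotations": npio.read_gmt(study_bundle.annotations),
        "pharm": npio.read_pharm_efficacy_table(study_bundle.pharm_efficacy),
    }


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory) -> dict[str, Path]:
    """A reduced input bundle for fast end-to-end pipeline tests."""
    out = tmp_path_factory.mktemp("small_bundle")
    cfg = synthetic.GeneratorConfig(
        seed=7,
        n_herbs=3,
        n_compounds=5,
        n_targets=30,
        n_disease_targets=5,
        n_shared_targets=2,
        n_other_proteins=60,
        ppi_mean_degree=8.0,
        promiscuous_target_count=2,
        n_terms=20,
        planted_term_size=10,
        planted_fold=3.0,
    )
    ct = synthetic.generate_compound_targets(cfg)
    rng = random.Random("small-bundle")
    shared = sorted(t for t in ct.targets if t.startswith("T"))[:2]
    disease = DiseaseTargetSet(shared + ["DIS01", "DIS02", "DIS03"])
    ppi = synthetic.generate_ppi(cfg, ct.targets | disease.targets)
    universe = {p for it in ppi for p in it.pair} | ct.targets | disease.targets
    hub = sorted(ct.targets)[:10]
    annotations = synthetic.generate_annotations(cfg, universe, hub)

    herb_rows = [
        (f"H{1 + i % cfg.n_herbs}", c) for i, c in enumerate(sorted(ct.compounds))
    ]
    paths = {
        "herb_compounds": out / "herb_compounds.tsv",
        "compound_targets": out / "compound_targets.tsv",
        "disease_targets": out / "disease_targets.tsv",
        "ppi_edges": out / "ppi_edges.tsv",
        "annotations": out / "annotations.gmt",
        "pharm_efficacy": out / "pharm_efficacy.tsv",
    }
    npio.write_relation_table(herb_rows, paths["herb_compounds"], ("herb_id", "compound_id"))
    npio.write_relation_table(sorted(ct.rows), paths["compound_targets"], ("compound_id", "target_id"))
    npio.write_relation_table([(t,) for t in disease], paths["disease_targets"], ("target_id",))
    npio.write_scored_interactions(ppi, paths["ppi_edges"])
    npio.write_gmt(annotations, paths["annotations"])
    npio.write_relation_table(
        [(sorted(ct.compounds)[0], "Scavenging free radical", "qi_dispersing")],
        paths["pharm_efficacy"],
        ("compound_id", "pharmacology_statement", "traditional_effect"),
    )
    return paths


def typed_network_from_graph(g: nx.Graph, role: str = "other_protein") -> TypedNetwork:
    """Wrap a plain graph, giving every node the same role."""
    net = TypedNetwork(name="test")
    for node in sorted(g.nodes, key=str):
        net.add_node(str(node), role)
    for u, v in g.edges:
        net.add_edge(str(u), str(v))
    return net


def random_small_graph(seed: int, max_nodes: int = 8) -> nx.Graph:
    """Random graph with 2..max_nodes nodes and varying density."""
    rng = random.Random(seed)
    n = rng.randint(2, max_nodes)
    p = rng.choice([0.15, 0.3, 0.5, 0.8])
    return nx.gnp_random_graph(n, p, seed=rng.randrange(2**31))
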