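"""Synthetic input generators for the pipeline.

The original study assembled its inputs from web services (pharmacophore
target prediction, a therapeutic-target database, a scored PPI
catalogue, a GO annotation service).  None of those query results were
deposited, so this module generates tables with the same cardinalities
and statistical structure instead:

* a bipartite compound->target relation with a right-skewed per-target
  compound count and a small block of "promiscuous" targets hit by every
  compound (the centre/periphery pattern of drug-target maps);
* a scale-free (preferential-attachment) PPI layer over the targets plus
  a pool of other human proteins, with i.i.d. uniform(0.15, 1.0)
  confidence scores so the standard >0.4 filter removes an analytically
  predictable ~29.4% of edges;
* GMT annotation sets with one or more planted over-represented terms of
  controlled fold enrichment, the rest sampled uniformly.

All generators are pure functions of their configuration: the same seed
always yields byte-identical tables.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx

from . import io as npio
from .model import (
    AnnotationCollection,
    AnnotationTerm,
    CompoundTargetTable,
    ConfigError,
    DiseaseTargetSet,
    HerbCompoundTable,
    PharmEfficacyRow,
    PharmEfficacyTable,
    ScoredInteraction,
    TypedNetwork,
)

__all__ = [
    "GeneratorConfig",
    "generate_compound_targets",
    "generate_ppi",
    "generate_hub_ppi",
    "generate_annotations",
    "study_scale_fixture",
    "main_subnetwork_fixture",
    "FIXTURE_HERB_COMPOUNDS",
    "FIXTURE_COMPOUNDS",
    "TABLE1_PHARM_EFFICACY",
]

# Success probability of the truncated-geometric per-target compound
# count.  With 11 compounds this gives a mean of ~4.5 compounds per
# non-promiscuous target, reproducing the observed ~1075-edge scale of
# the 11x233 bipartite map.
_BIPARTITE_GEOM_P = 0.15

#: Promiscuous targets keep the symbols reported as being hit by all
#: eleven compounds, for readable fixtures; extras get HUBnnnn tokens.
PROMISCUOUS_SYMBOLS = ("AR", "BACE1", "CA2", "GSTA1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic tables.

    Defaults reproduce the published censuses: 6 herbs, 11 active
    compounds, 233 predicted targets (4 of them hit by all compounds),
    9 disease targets of which 2 are shared with the compound-target
    set, and 1259 other human proteins in the PPI layer.
    ``ppi_mean_degree`` is calibrated so that the >0.4 confidence filter
    leaves a network at the published ~55k-edge scale.
    """

    seed: int = 0
    n_herbs: int = 6
    n_compounds: int = 11
    n_targets: int = 233
    n_disease_targets: int = 9
    n_shared_targets: int = 2
    n_other_proteins: int = 1259
    ppi_mean_degree: float = 108.0
    promiscuous_target_count: int = 4
    n_terms: int = 50
    planted_term_size: int = 30
    planted_fold: float = 7.1

    def validate(self) -> None:
        counts = {
            "n_herbs": self.n_herbs,
            "n_compounds": self.n_compounds,
            "n_targets": self.n_targets,
            "n_disease_targets": self.n_disease_targets,
            "n_shared_targets": self.n_shared_targets,
            "n_other_proteins": self.n_other_proteins,
            "promiscuous_target_count": self.promiscuous_target_count,
            "n_terms": self.n_terms,
            "planted_term_size": self.planted_term_size,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigError(f"{name} must be >= 0, got {value}")
        if self.n_shared_targets > min(self.n_targets, self.n_disease_targets):
            raise ConfigError(
                "n_shared_targets exceeds min(n_targets, n_disease_targets)"
            )
        if self.promiscuous_target_count > self.n_targets:
            raise ConfigError(
                f"promiscuous_target_count={self.promiscuous_target_count} "
                f"exceeds n_targets={self.n_targets}"
            )
        if self.ppi_mean_degree <= 0:
            raise ConfigError("ppi_mean_degree must be positive")
        if self.planted_fold < 1.0:
            raise ConfigError("planted_fold must be >= 1")


def _rng(cfg: GeneratorConfig, stream: str) -> random.Random:
    # independent stream per generator; string seeding is deterministic
    return random.Random(f"netpharm:{cfg.seed}:{stream}")


def _trunc_geometric(rng: random.Random, p: float, upper: int) -> int:
    """Geometric(p) on {1, 2, ...} truncated to [1, upper], by inverse CDF."""
    if upper <= 1:
        return 1
    q = 1.0 - p
    u = rng.random()
    # P(X <= k) = (1 - q^k) / (1 - q^upper) for the truncated law
    k = math.ceil(math.log1p(-u * (1.0 - q**upper)) / math.log(q))
    return min(max(k, 1), upper)


# ---------------------------------------------------------------------------
# bipartite compound->target table
# ---------------------------------------------------------------------------

def generate_compound_targets(
    cfg: GeneratorConfig,
    compound_names: Optional[Sequence[str]] = None,
) -> CompoundTargetTable:
    """Generate the bipartite compound->target relation.

    Exactly ``cfg.promiscuous_target_count`` targets are hit by every
    compound; the remaining targets receive a compound count drawn from
    a right-skewed truncated-geometric law on [1, n_compounds].  Every
    compound hits at least one target and every target is hit at least
    once.
    """
    cfg.validate()
    if cfg.n_compounds < 1 or cfg.n_targets < 1:
        raise ConfigError("need at least one compound and one target")
    if compound_names is not None and len(compound_names) != cfg.n_compounds:
        raise ConfigError(
            f"{len(compound_names)} compound names given for "
            f"n_compounds={cfg.n_compounds}"
        )
    rng = _rng(cfg, "compound_targets")
    compounds = (
        list(compound_names)
        if compound_names is not None
        else [f"C{i + 1:02d}" for i in range(cfg.n_compounds)]
    )
    hub_names = list(PROMISCUOUS_SYMBOLS[: cfg.promiscuous_target_count])
    hub_names += [
        f"HUB{i + 1:04d}" for i in range(len(hub_names), cfg.promiscuous_target_count)
    ]
    other_names = [
        f"T{i + 1:04d}" for i in range(cfg.n_targets - cfg.promiscuous_target_count)
    ]

    rows: list[tuple[str, str]] = []
    for target in hub_names:
        for compound in compounds:
            rows.append((compound, target))
    for target in other_names:
        k = _trunc_geometric(rng, _BIPARTITE_GEOM_P, cfg.n_compounds)
        for compound in rng.sample(compounds, k):
            rows.append((compound, target))

    covered = {c for c, _ in rows}
    for compound in compounds:
        if compound not in covered and other_names:
            rows.append((compound, rng.choice(other_names)))
    return CompoundTargetTable(sorted(set(rows)))


# ---------------------------------------------------------------------------
# PPI layers
# ---------------------------------------------------------------------------

def generate_ppi(
    cfg: GeneratorConfig, anchor_nodes: Iterable[str]
) -> list[ScoredInteraction]:
    """Scale-free PPI over the anchors plus ``cfg.n_other_proteins`` novel proteins.

    A Barabási–Albert preferential-attachment graph is built over all
    nodes (anchors shuffled uniformly among the attachment positions)
    and each edge receives an i.i.d. uniform(0.15, 1.0) confidence
    score.  Scores are NOT pre-filtered; apply the >0.4 cut downstream.
    """
    cfg.validate()
    rng = _rng(cfg, "ppi")
    anchors = sorted({a.strip().upper() for a in anchor_nodes})
    others = [f"P{i + 1:04d}" for i in range(cfg.n_other_proteins)]
    clash = set(anchors) & set(others)
    if clash:
        raise ConfigError(f"anchor symbols clash with generated names: {sorted(clash)}")
    names = anchors + others
    n = len(names)
    if n == 0:
        return []
    rng.shuffle(names)
    m = max(1, round(cfg.ppi_mean_degree / 2.0))
    if n <= m + 1:
        g = nx.complete_graph(n)
    else:
        g = nx.barabasi_albert_graph(n, m, seed=rng.randrange(2**31))
    interactions = [
        ScoredInteraction(names[u], names[v], rng.uniform(0.15, 1.0))
        for u, v in g.edges()
    ]
    return npio.canonicalize_interactions(interactions)


def generate_hub_ppi(
    seed: int,
    n_nodes: int = 300,
    n_hubs: int = 8,
    hub_attach_frac: float = 0.8,
    bg_mean_degree: float = 3.0,
) -> tuple[list[ScoredInteraction], frozenset[str]]:
    """PPI with an unambiguous planted hub set, for hub-recovery tests.

    Hubs form a clique and each attaches to ``hub_attach_frac`` of all
    other nodes; the background is sparse Erdős–Rényi.  Returns the
    scored edge list together with the ground-truth hub symbols.
    """
    if not 0 < n_hubs < n_nodes:
        raise ConfigError("need 0 < n_hubs < n_nodes")
    rng = random.Random(f"netpharm:{seed}:hub_ppi")
    hubs = [f"HUB{i + 1:03d}" for i in range(n_hubs)]
    others = [f"N{i + 1:04d}" for i in range(n_nodes - n_hubs)]
    edges: set[tuple[str, str]] = set()
    for i, h in enumerate(hubs):
        for h2 in hubs[i + 1 :]:
            edges.add((h, h2))
        n_attach = round(hub_attach_frac * len(others))
        for other in rng.sample(others, n_attach):
            edges.add((h, other))
    p_bg = min(1.0, bg_mean_degree / max(1, len(others) - 1))
    for i, a in enumerate(others):
        for b in others[i + 1 :]:
            if rng.random() < p_bg:
                edges.add((a, b))
    interactions = [
        ScoredInteraction(a, b, rng.uniform(0.15, 1.0)) for a, b in sorted(edges)
    ]
    return npio.canonicalize_interactions(interactions), frozenset(hubs)


# ---------------------------------------------------------------------------
# annotation sets
# ---------------------------------------------------------------------------

def max_attainable_fold(
    n_list: int, chunk: int, term_size: int, n_universe: int
) -> float:
    """Largest fold enrichment a planted term can realize."""
    return min(chunk, term_size) * n_universe / (n_list * term_size)


def generate_annotations(
    cfg: GeneratorConfig,
    universe: Iterable[str],
    hub_set: Iterable[str],
    n_planted: int = 1,
    planted_names: Optional[Sequence[str]] = None,
) -> AnnotationCollection:
    """Annotation sets with planted over-represented term(s).

    Each planted term overlaps ``hub_set`` so that its realized fold
    enrichment against the hub list — (k/n)/(K/N) — matches
    ``cfg.planted_fold`` up to integer rounding (within ±10% whenever
    sizes allow).  With ``n_planted > 1`` the hub set is split into
    disjoint chunks, one planted term per chunk, so a module-partition
    step can recover the planted bipartition.  The remaining terms are
    sampled uniformly from the universe.
    """
    cfg.validate()
    rng = _rng(cfg, "annotations")
    universe_l = sorted({g.strip().upper() for g in universe})
    hub_l = sorted({g.strip().upper() for g in hub_set})
    if not set(hub_l) <= set(universe_l):
        raise ConfigError("hub_set must be a subset of the universe")
    if n_planted < 1 or n_planted > cfg.n_terms:
        raise ConfigError("need 1 <= n_planted <= n_terms")
    if n_planted > len(hub_l):
        raise ConfigError("more planted terms than hub genes")

    N, n, K, fold = len(universe_l), len(hub_l), cfg.planted_term_size, cfg.planted_fold
    shuffled = hub_l[:]
    rng.shuffle(shuffled)
    chunk_size = len(shuffled) // n_planted
    chunks = [
        shuffled[i * chunk_size : (i + 1) * chunk_size if i < n_planted - 1 else None]
        for i in range(n_planted)
    ]

    background = sorted(set(universe_l) - set(hub_l))
    terms: list[AnnotationTerm] = []
    for i, chunk in enumerate(chunks):
        k = round(fold * n * K / N)
        cap = min(len(chunk), K)
        if k > cap:
            attainable = max_attainable_fold(n, len(chunk), K, N)
            raise ConfigError(
                f"planted_fold={fold} unattainable: needs k={k} of a "
                f"{len(chunk)}-gene chunk (max attainable fold "
                f"{attainable:.2f})"
            )
        k = max(k, 1)
        # integer k alone can miss the requested fold badly when k is
        # small; re-fitting the term size K around it realizes the fold
        # to within the granularity of one gene
        K_i = min(max(k, round(k * N / (n * fold))), N - 1)
        if K_i - k > len(background):
            raise ConfigError("universe too small to pad the planted term")
        members = rng.sample(chunk, k) + rng.sample(background, K_i - k)
        name = (
            planted_names[i]
            if planted_names is not None and i < len(planted_names)
            else f"planted module {i + 1}"
        )
        terms.append(
            AnnotationTerm(
                term_id=f"PLT:{i + 1:04d}", name=name, members=frozenset(members)
            )
        )

    lo, hi = max(5, K // 2), min(N, 2 * K)
    for j in range(cfg.n_terms - n_planted):
        size = rng.randint(lo, max(lo, hi))
        members = rng.sample(universe_l, size)
        terms.append(
            AnnotationTerm(
                term_id=f"SYN:{j + 1:04d}",
                name=f"random gene set {j + 1}",
                members=frozenset(members),
            )
        )
    return AnnotationCollection(terms)


# ---------------------------------------------------------------------------
# curated formula fixture (herbs, compounds, pharmacology)
# ---------------------------------------------------------------------------

#: Herb -> active-compound assignment of the six-herb formula.  The
#: pharmacophore-mapping step substituted saikosaponin a/d for
#: saikosaponin and paeoniflorin for total glucosides of peony, so the
#: compound-target table uses the substituted identifiers.
FIXTURE_HERB_COMPOUNDS: tuple[tuple[str, str], ...] = (
    ("chai_hu", "saikosaponin_a"),
    ("chai_hu", "saikosaponin_d"),
    ("chai_hu", "longispinogenin"),
    ("dang_gui", "ferulic_acid"),
    ("dang_gui", "ligustilide"),
    ("bai_shao", "paeoniflorin"),
    ("bai_zhu", "atractylol"),
    ("bai_zhu", "atractylenolide_I"),
    ("bai_zhu", "atractylenolide_III"),
    ("fu_ling", "pachyman"),
    ("fu_ling", "pachymic_acid"),
    ("gan_cao", "glycyrrhizin"),
)

#: The eleven compounds carried into target prediction (longispinogenin
#: has no reported pharmacology or predicted targets and is left out).
FIXTURE_COMPOUNDS: tuple[str, ...] = (
    "saikosaponin_a",
    "saikosaponin_d",
    "ferulic_acid",
    "ligustilide",
    "paeoniflorin",
    "atractylol",
    "atractylenolide_I",
    "atractylenolide_III",
    "pachyman",
    "pachymic_acid",
    "glycyrrhizin",
)

_T1 = [
    # (compound, statement, effect)
    ("saikosaponin_a", "Increasing IL-2 and IgM level", "qi_dispersing"),
    ("saikosaponin_a", "Reducing LPO", "qi_dispersing"),
    ("saikosaponin_a", "Keeping a balance of TH/TS", "blood_nourishing"),
    ("saikosaponin_d", "Increasing IL-2 and IgM level", "qi_dispersing"),
    ("saikosaponin_d", "Reducing LPO", "qi_dispersing"),
    ("saikosaponin_d", "Keeping a balance of TH/TS", "blood_nourishing"),
    ("ferulic_acid", "Decreasing LPO and MDA", "qi_dispersing"),
    ("ferulic_acid", "Balancing TXA2/PGI2", "qi_dispersing"),
    ("ferulic_acid", "Reducing blood viscosity", "qi_dispersing"),
    ("ferulic_acid", "Increasing SOD activity", "spleen_invigorating"),
    ("ferulic_acid", "Enhancing hematopoietic function", "blood_nourishing"),
    ("ferulic_acid", "Keeping the balance of TXB2/6-keto-PGF1a", "spleen_invigorating"),
    ("ligustilide", "Decreasing MDA", "qi_dispersing"),
    ("ligustilide", "Balancing TXA2/PGI2", "qi_dispersing"),
    ("ligustilide", "Reducing blood viscosity", "qi_dispersing"),
    ("ligustilide", "Increasing activity of SOD and GSH-PX", "blood_nourishing"),
    ("paeoniflorin", "Decreasing MDA", "qi_dispersing"),
    ("paeoniflorin", "Reducing blood viscosity", "qi_dispersing"),
    ("paeoniflorin", "Balancing TXA2/PGI2", "qi_dispersing"),
    ("paeoniflorin", "Increasing IL-2 and IgM level", "qi_dispersing"),
    ("paeoniflorin", "Keeping a balance of TH/TS", "blood_nourishing"),
    ("paeoniflorin", "Increasing activity of SOD and GSH-PX", "blood_nourishing"),
    ("paeoniflorin", "Enhancing hematopoietic function", "blood_nourishing"),
    ("paeoniflorin", "Improving the quality of erythrocytes", "blood_nourishing"),
    ("atractylenolide_I", "Strengthening digestion and absorption", "spleen_invigorating"),
    ("atractylenolide_I", "Enhancing salivary amylase activity", "spleen_invigorating"),
    ("atractylenolide_I", "Slowing the heart rate", "spleen_invigorating"),
    ("atractylenolide_III", "Strengthening digestion and absorption", "spleen_invigorating"),
    ("pachyman", "Scavenging free radical", "qi_dispersing"),
    ("pachyman", "Reducing LPO and MDA", "qi_dispersing"),
    ("pachyman", "Lowering blood sugar", "qi_dispersing"),
    ("pachyman", "Increasing SOD activity", "spleen_invigorating"),
    ("glycyrrhizin", "Reducing MDA", "qi_dispersing"),
    ("glycyrrhizin", "Increasing IL-1b, IL-6, IL-10", "qi_dispersing"),
    ("glycyrrhizin", "Scavenging free radical", "qi_dispersing"),
    ("glycyrrhizin", "Increasing SOD activity", "spleen_invigorating"),
    ("glycyrrhizin", "Increasing the plasma TP", "spleen_invigorating"),
]

#: Curated pharmacology -> traditional-effect table.  Pachymic acid and
#: the two compounds without reported pharmacology have no rows.
TABLE1_PHARM_EFFICACY = PharmEfficacyTable(PharmEfficacyRow(*r) for r in _T1)

#: Disease (infertility) targets of the curated fixture: two are shared
#: with the compound-target set (relabelled inside it), seven are
#: therapeutic-target-database entries of their own.  AMH is engineered
#: to lack target-level PPI support above the confidence cutoff.
FIXTURE_SHARED_DISEASE = ("ESR1", "PGR")
FIXTURE_PURE_DISEASE = ("FSHR", "LHCGR", "GNRHR", "PRLR", "SHBG", "INHBA", "AMH")
FIXTURE_UNSUPPORTED_DISEASE = "AMH"

#: Fig-6-style functional-module names planted into the fixture GMT.
FIXTURE_MODULE_TERMS = (
    ("GO:0048545", "response to steroid hormone stimulus"),
    ("GO:0030518", "steroid hormone receptor signaling pathway"),
    ("GO:0043627", "response to estrogen stimulus"),
    ("GO:0032868", "response to insulin stimulus"),
)


@dataclass(frozen=True)
class FixtureBundle:
    """Paths and ground-truth metadata of a generated input bundle."""

    directory: Path
    herb_compounds: Path
    compound_targets: Path
    disease_targets: Path
    ppi_edges: Path
    annotations: Path
    pharm_efficacy: Path
    ground_truth: Path


def study_scale_fixture(seed: int, out_dir: "Path | str") -> FixtureBundle:
    """Write a full input bundle at the published cardinalities.

    Produces 6 herbs, 11 compounds, 233 predicted targets (2 of them
    shared with the 9-entry disease list), 1259 other proteins in the
    PPI layer, the curated pharmacology table, and a GMT with the four
    planted functional-module terms.  Deterministic: the same seed
    yields a byte-identical bundle.
    """
    cfg = GeneratorConfig(seed=seed)
    rng = _rng(cfg, "fixture")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ct = generate_compound_targets(cfg, compound_names=FIXTURE_COMPOUNDS)

    # Relabel two generated targets to the shared disease symbols.
    plain = sorted(t for t in ct.targets if t.startswith("T"))
    relabel = dict(zip(rng.sample(plain, len(FIXTURE_SHARED_DISEASE)), FIXTURE_SHARED_DISEASE))
    ct = CompoundTargetTable(
        sorted((c, relabel.get(t, t)) for c, t in ct.rows)
    )
    disease = DiseaseTargetSet(FIXTURE_SHARED_DISEASE + FIXTURE_PURE_DISEASE)

    anchors = ct.targets | disease.targets
    interactions = generate_ppi(cfg, anchors)
    interactions = _engineer_ppi(interactions, ct.targets, disease, rng)

    # Universe = every protein of the (filtered) interaction layer plus
    # the anchors themselves.
    universe: set[str] = set(anchors)
    for it in interactions:
        universe.add(it.protein_a)
        universe.add(it.protein_b)

    # Plant the four functional modules on the best-supported targets:
    # the 40 compound targets of highest filtered PPI degree.
    deg: dict[str, int] = {}
    for it in interactions:
        if it.score > 0.4:
            deg[it.protein_a] = deg.get(it.protein_a, 0) + 1
            deg[it.protein_b] = deg.get(it.protein_b, 0) + 1
    hub_set = sorted(ct.targets, key=lambda t: (-deg.get(t, 0), t))[:40]
    annotations = generate_annotations(
        cfg,
        universe,
        hub_set,
        n_planted=len(FIXTURE_MODULE_TERMS),
        planted_names=[name for _, name in FIXTURE_MODULE_TERMS],
    )

    bundle = FixtureBundle(
        directory=out,
        herb_compounds=out / "herb_compounds.tsv",
        compound_targets=out / "compound_targets.tsv",
        disease_targets=out / "disease_targets.tsv",
        ppi_edges=out / "ppi_edges.tsv",
        annotations=out / "annotations.gmt",
        pharm_efficacy=out / "pharm_efficacy.tsv",
        ground_truth=out / "ground_truth.json",
    )
    npio.write_relation_table(
        sorted(FIXTURE_HERB_COMPOUNDS), bundle.herb_compounds, ("herb_id", "compound_id")
    )
    npio.write_relation_table(
        sorted(ct.rows), bundle.compound_targets, ("compound_id", "target_id")
    )
    npio.write_relation_table(
        [(t,) for t in sorted(disease.targets)], bundle.disease_targets, ("target_id",)
    )
    npio.write_scored_interactions(interactions, bundle.ppi_edges)
    npio.write_gmt(annotations, bundle.annotations)
    npio.write_pharm_efficacy_table(TABLE1_PHARM_EFFICACY, bundle.pharm_efficacy)
    truth = {
        "seed": seed,
        "config": asdict(cfg),
        "shared_disease_targets": sorted(FIXTURE_SHARED_DISEASE),
        "unsupported_disease_target": FIXTURE_UNSUPPORTED_DISEASE,
        "planted_terms": {tid: name for tid, name in FIXTURE_MODULE_TERMS},
        "planted_hub_genes": hub_set,
    }
    bundle.ground_truth.write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return bundle


def _engineer_ppi(
    interactions: list[ScoredInteraction],
    compound_targets: set[str],
    disease: DiseaseTargetSet,
    rng: random.Random,
) -> list[ScoredInteraction]:
    """Adjust the raw PPI so the filtered network hits the fixed censuses.

    Three deterministic repairs: (a) the designated unsupported disease
    target keeps no above-cutoff edge to any target, so it drops out of
    the herb-target-disease network yet remains a seed of the PPI
    network; (b) every other pure disease target keeps at least one
    above-cutoff edge to a compound target; (c) every non-seed protein
    keeps at least one above-cutoff edge to a seed so the seed
    neighbourhood spans the full protein pool.
    """
    seeds = compound_targets | disease.targets
    target_space = compound_targets | disease.targets
    others = sorted(
        {p for it in interactions for p in it.pair if p not in seeds}
    )
    by_pair: dict[tuple[str, str], float] = {it.pair: it.score for it in interactions}

    unsupported = FIXTURE_UNSUPPORTED_DISEASE
    for pair in sorted(by_pair):
        if unsupported in pair:
            partner = pair[0] if pair[1] == unsupported else pair[1]
            if partner in target_space and by_pair[pair] > 0.4:
                by_pair[pair] = rng.uniform(0.15, 0.4)
    if not any(
        unsupported in pair and by_pair[pair] > 0.4 for pair in by_pair
    ):
        partner = rng.choice(others)
        by_pair[tuple(sorted((unsupported, partner)))] = rng.uniform(0.45, 1.0)

    ct_sorted = sorted(compound_targets)
    for dt in sorted(disease.targets - compound_targets):
        if dt == unsupported:
            continue
        supported = any(
            dt in pair
            and by_pair[pair] > 0.4
            and (pair[0] if pair[1] == dt else pair[1]) in compound_targets
            for pair in by_pair
        )
        if not supported:
            partner = rng.choice(ct_sorted)
            by_pair[tuple(sorted((dt, partner)))] = rng.uniform(0.45, 1.0)

    seed_sorted = sorted(seeds)
    covered: set[str] = set()
    for (a, b), score in by_pair.items():
        if score > 0.4:
            if a in seeds and b not in seeds:
                covered.add(b)
            elif b in seeds and a not in seeds:
                covered.add(a)
    for orphan in others:
        if orphan not in covered:
            partner = rng.choice(seed_sorted)
            if partner == unsupported:  # keep repair (a) intact
                partner = rng.choice(ct_sorted)
            by_pair[tuple(sorted((orphan, partner)))] = rng.uniform(0.45, 1.0)

    return npio.canonicalize_interactions(
        ScoredInteraction(a, b, s) for (a, b), s in by_pair.items()
    )


# ---------------------------------------------------------------------------
# engineered main-node subnetwork fixture
# ---------------------------------------------------------------------------

def main_subnetwork_fixture(
    seed: int,
) -> tuple[TypedNetwork, frozenset[str], dict[str, int]]:
    """Network + main-node set engineered to the published hub-subnetwork census.

    235 main nodes are planted in a larger network so that exactly 112
    of them interact with another main node, with role census
    31 compound targets, 1 infertility target, 1 shared target and 79
    other proteins; the remaining 123 main nodes touch only non-main
    satellites and therefore vanish when the direct-interaction
    subnetwork drops isolates.  Returns (network, main set, expected
    census of the surviving subnetwork).
    """
    rng = random.Random(f"netpharm:{seed}:subnet_fixture")
    expected = {
        "compound_target": 31,
        "infertility_target": 1,
        "shared_target": 1,
        "other_protein": 79,
    }
    connected: list[tuple[str, str]] = []
    for role, count in expected.items():
        for i in range(count):
            connected.append((f"{role.upper()}_{i + 1:03d}", role))
    # 123 further main nodes whose only contacts are non-main satellites
    lonely = [(f"LONE_{i + 1:03d}", "other_protein") for i in range(104)]
    lonely += [(f"LONE_CT_{i + 1:03d}", "compound_target") for i in range(17)]
    lonely += [("LONE_IT_001", "infertility_target"), ("LONE_ST_001", "shared_target")]
    satellites = [(f"SAT_{i + 1:03d}", "other_protein") for i in range(50)]

    net = TypedNetwork(name="engineered_main_subnetwork")
    for node, role in connected + lonely + satellites:
        net.add_node(node, role)

    ids = [node for node, _ in connected]
    rng.shuffle(ids)
    for a, b in zip(ids, ids[1:]):  # a random spanning path keeps all 112 non-isolated
        net.add_edge(a, b)
    for _ in range(3 * len(ids)):
        a, b = rng.sample(ids, 2)
        net.add_edge(a, b)
    sat_ids = [node for node, _ in satellites]
    for node, _ in lonely:
        for partner in rng.sample(sat_ids, rng.randint(1, 3)):
            net.add_edge(node, partner)

    main = frozenset(node for node, _ in connected + lonely)
    return net, main, expected
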