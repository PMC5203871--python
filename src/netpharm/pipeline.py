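"""End-to-end pipeline: inputs -> networks -> topology -> hubs -> enrichment.

One configured run builds the four typed networks, scores networks
(2)-(4) topologically, selects main nodes of the PPI network, induces
their direct-interaction subnetwork, runs over-representation analysis
for the herb-target-disease gene set and for the main-node set,
partitions the latter into functional modules, and records every
artifact with a content hash in a run manifest.  Identical config and
seed produce identical manifest hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from . import io as npio
from . import networks, synthetic, topology
from .enrichment import enrich, filter_significant, partition_modules
from .model import (
    EnrichmentResult,
    ModulePartition,
    NetpharmError,
    TypedNetwork,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ValidationReport", "validate_inputs", "run_pipeline"]

_INPUT_KEYS = (
    "herb_compounds",
    "compound_targets",
    "disease_targets",
    "ppi_edges",
    "annotations",
    "pharm_efficacy",
)


@dataclass
class PipelineConfig:
    """Every tunable of a run, with the study-era defaults surfaced.

    When ``generate`` is true the input bundle is synthesized at the
    published cardinalities under ``<out_dir>/inputs`` before the run.
    """

    out_dir: Path
    seed: int = 0
    generate: bool = False
    herb_compounds: Optional[Path] = None
    compound_targets: Optional[Path] = None
    disease_targets: Optional[Path] = None
    ppi_edges: Optional[Path] = None
    annotations: Optional[Path] = None
    pharm_efficacy: Optional[Path] = None
    score_threshold: float = 0.4
    p_cut: float = 0.05
    fe_cut: float = 1.0
    k_modules: int = 4
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for key in _INPUT_KEYS:
            value = getattr(self, key)
            if value is not None:
                setattr(self, key, Path(value))
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValidationError("score_threshold must lie in [0, 1]")
        if self.k_modules < 1:
            raise ValidationError("k_modules must be >= 1")

    @classmethod
    def from_yaml(cls, path: "Path | str") -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ValidationError("config must set out_dir")
        return cls(**raw)

    def input_paths(self) -> dict[str, Path]:
        out = {}
        for key in _INPUT_KEYS:
            value = getattr(self, key)
            if value is None:
                raise ValidationError(f"input path {key!r} is not set")
            out[key] = value
        return out


@dataclass
class ValidationReport:
    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_inputs(cfg: PipelineConfig) -> ValidationReport:
    """Cross-file referential checks on a configured input bundle."""
    report = ValidationReport()
    try:
        paths = cfg.input_paths()
    except ValidationError as exc:
        report.fatal.append(str(exc))
        return report
    for key, path in paths.items():
        if not path.exists():
            report.fatal.append(f"missing input file {key}: {path}")
    if report.fatal:
        return report

    herbs = npio.read_herb_compound_table(paths["herb_compounds"])
    ct = npio.read_compound_target_table(paths["compound_targets"])
    if not herbs.rows:
        report.fatal.append("herb/compound table is empty")
    if not ct.rows:
        report.fatal.append("compound/target table is empty")
    if report.fatal:
        return report

    orphan = ct.compounds - herbs.compounds
    if orphan:
        report.fatal.append(
            f"compound(s) in target table absent from herb table: {sorted(orphan)}"
        )
    raw_disease = [
        t for (t,) in npio.read_relation_table(paths["disease_targets"], ("target_id",))
    ]
    if not raw_disease:
        report.fatal.append("disease target list is empty")
    else:
        lowercase = sorted({t for t in raw_disease if t != t.upper()})
        if lowercase:
            report.warnings.append(
                f"disease symbols normalized to uppercase: {lowercase}"
            )
        shared = {t.upper() for t in raw_disease} & ct.targets
        logger.info(
            "validate: %d disease target(s), %d shared with the compound-target set",
            len(set(t.upper() for t in raw_disease)),
            len(shared),
        )
    return report


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _export_network(net: TypedNetwork, stem: Path) -> list[Path]:
    sif, graphml = stem.with_suffix(".sif"), stem.with_suffix(".graphml")
    npio.write_sif(net, sif)
    npio.write_graphml(net, graphml)
    return [sif, graphml]


def write_enrichment_results(
    results: list[EnrichmentResult],
    path: Path,
    partition: Optional[ModulePartition] = None,
) -> None:
    """TSV export: fold enrichment to 3 dp, p values in scientific notation."""
    module_of_term = {}
    if partition is not None:
        labels = set(partition.labels)
        for res in results:
            if res.term_name in labels:
                module_of_term[res.term_id] = res.term_name
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "term_id\tterm_name\tk\tn\tK\tN\tfold_enrichment\tp_raw\tq_bh\tmodule\n"
        )
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.term_name}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                f"{r.fold_enrichment:.3f}\t{r.p_raw:.3g}\t{r.q_bh:.3g}\t"
                f"{module_of_term.get(r.term_id, '')}\n"
            )


def run_pipeline(cfg: PipelineConfig, force: bool = False) -> dict:
    """Execute every stage and return the run manifest.

    A stage failure aborts with the stage name; artifacts of completed
    stages are left on disk.  Non-fatal validation findings stop the run
    unless ``force`` is true.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    counts: dict[str, object] = {}
    stage = "setup"
    try:
        if cfg.generate:
            stage = "generate"
            bundle = synthetic.study_scale_fixture(cfg.seed, out / "inputs")
            for key in _INPUT_KEYS:
                setattr(cfg, key, getattr(bundle, key))
            artifacts.extend(getattr(bundle, key) for key in _INPUT_KEYS)

        stage = "validate"
        report = validate_inputs(cfg)
        if report.fatal:
            raise ValidationError("; ".join(report.fatal))
        if report.warnings:
            for w in report.warnings:
                logger.warning("validate: %s", w)
            if not force:
                raise ValidationError(
                    "non-fatal validation issues (rerun with force=True): "
                    + "; ".join(report.warnings)
                )

        stage = "load"
        paths = cfg.input_paths()
        herbs = npio.read_herb_compound_table(paths["herb_compounds"])
        ct = npio.read_compound_target_table(paths["compound_targets"])
        disease = npio.read_disease_targets(paths["disease_targets"])
        pharm = npio.read_pharm_efficacy_table(paths["pharm_efficacy"])
        annotations = npio.read_gmt(paths["annotations"])
        ppi = npio.read_scored_interactions(
            paths["ppi_edges"], min_score=cfg.score_threshold
        )

        stage = "networks"
        net1 = networks.build_pharm_efficacy_network(pharm, herbs)
        net2 = networks.build_compound_target_network(ct)
        net3 = networks.build_herb_target_disease_network(herbs, ct, disease, ppi)
        net4 = networks.build_ppi_network(ct, disease, ppi)
        built = {
            "pharm_efficacy": net1,
            "compound_target": net2,
            "herb_target_disease": net3,
            "ppi": net4,
        }
        for name, net in built.items():
            artifacts.extend(_export_network(net, out / name))
            counts[f"{name}_nodes"] = net.number_of_nodes()
            counts[f"{name}_edges"] = net.number_of_edges()
            counts[f"{name}_roles"] = dict(sorted(net.role_census().items()))
            logger.info(
                "network %s: %d nodes %d edges, roles %s",
                name,
                net.number_of_nodes(),
                net.number_of_edges(),
                counts[f"{name}_roles"],
            )

        stage = "topology"
        thresholds_all: dict[str, dict[str, float]] = {}
        main_nodes: set[str] = set()
        for name in ("compound_target", "herb_target_disease", "ppi"):
            records, thresholds, selected = topology.analyze(built[name])
            table = out / f"{name}_topology.tsv"
            npio.write_node_attributes(records, table)
            artifacts.append(table)
            thresholds_all[name] = {
                "mean_degree": thresholds.mean_degree,
                "mean_betweenness": thresholds.mean_betweenness,
                "mean_closeness": thresholds.mean_closeness,
                "n_main_nodes": len(selected),
            }
            if name == "ppi":
                main_nodes = selected
        thresholds_path = out / "thresholds.json"
        thresholds_path.write_text(
            json.dumps(thresholds_all, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        artifacts.append(thresholds_path)
        counts["ppi_main_nodes"] = len(main_nodes)
        logger.info(
            "ppi main nodes: %d of %d (thresholds %s)",
            len(main_nodes),
            built["ppi"].number_of_nodes(),
            thresholds_all["ppi"],
        )

        stage = "hubs"
        main_path = out / "main_nodes.txt"
        main_path.write_text(
            "\n".join(sorted(main_nodes)) + "\n", encoding="utf-8"
        )
        artifacts.append(main_path)

        stage = "subnetwork"
        subnet = networks.main_node_subnetwork(built["ppi"], main_nodes)
        artifacts.extend(_export_network(subnet, out / "main_subnetwork"))
        counts["main_subnetwork_nodes"] = subnet.number_of_nodes()
        counts["main_subnetwork_edges"] = subnet.number_of_edges()
        counts["main_subnetwork_roles"] = dict(sorted(subnet.role_census().items()))

        stage = "enrichment"
        universe = annotations.annotated_genes & set(built["ppi"].nodes())
        target_roles = {"compound_target", "shared_target", "infertility_target"}
        fig4_genes = {
            n for n in built["herb_target_disease"].nodes()
            if built["herb_target_disease"].role_of(n) in target_roles
        } & universe
        results_a = enrich(fig4_genes, annotations, universe)
        write_enrichment_results(results_a, out / "enrichment_targets.tsv")
        artifacts.append(out / "enrichment_targets.tsv")

        main_genes = main_nodes & universe
        results_b = enrich(main_genes, annotations, universe)
        significant = filter_significant(results_b, cfg.p_cut, cfg.fe_cut)
        partition = partition_modules(
            main_genes, significant, cfg.k_modules, annotations
        )
        write_enrichment_results(results_b, out / "enrichment_main_nodes.tsv", partition)
        artifacts.append(out / "enrichment_main_nodes.tsv")
        modules_path = out / "modules.json"
        modules_path.write_text(
            json.dumps(
                {label: sorted(genes) for label, genes in partition.modules.items()},
                indent=2,
                sort_keys=True,
            )
            + "\n",
            encoding="utf-8",
        )
        artifacts.append(modules_path)
        counts["n_significant_terms_main"] = len(significant)
        counts["n_modules"] = len(
            [label for label in partition.labels if label != "unassigned"]
        )

        stage = "manifest"
        manifest = {
            "seed": cfg.seed,
            "config": {
                "score_threshold": cfg.score_threshold,
                "p_cut": cfg.p_cut,
                "fe_cut": cfg.fe_cut,
                "k_modules": cfg.k_modules,
                "generate": cfg.generate,
            },
            "counts": counts,
            "thresholds": thresholds_all,
            "artifacts": {
                str(p.relative_to(out)): _sha256(p) for p in sorted(set(artifacts))
            },
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        return manifest
    except NetpharmError as exc:
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
    except Exception as exc:  # pragma: no cover - defensive
        raise NetpharmError(f"stage {stage!r} failed: {exc}") from exc
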