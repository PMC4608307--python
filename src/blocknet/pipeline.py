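"""End-to-end orchestration: inputs (read or simulate) -> differential
expression -> Venn/cluster -> enrichment/augmentation -> network
centrality ranking, persisted as a structured report directory.

Every intermediate is a TSV; ``report.json`` carries the echoed
parameters, per-stage summary counts, the top-ranked gene lists and a
sha256 manifest of all produced files.  Given the same config and seed
the whole directory is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import de, enrichment, network, set_analysis, simulate
from .io import (
    AnnotationCatalog,
    ExpressionStudy,
    ValidationError,
    collapse_replicates,
    read_annotations,
    read_edge_table,
    read_expression_study,
    replicate_concordance,
    write_edge_table,
    write_expression_study,
    write_gmt,
)

log = logging.getLogger("blocknet")

FLOAT_FMT = "%.10g"


class StageError(RuntimeError):
    """Failure inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class IntegrityError(RuntimeError):
    """Report directory does not match its stored manifest."""


@dataclass
class PipelineConfig:
    outdir: str = "blocknet_out"
    seed: int = 0
    # either a simulation block or the four input paths
    simulation: simulate.SimulationConfig | None = None
    matrix_path: str | None = None
    samples_path: str | None = None
    annotations_path: str | None = None
    annotations_format: str = "gmt"
    edges_path: str | None = None
    # analysis parameters
    thresholds: de.DEThresholds = field(default_factory=de.DEThresholds)
    floor: float = 1.0
    q_max: float = 0.05
    min_k: int = 2
    augment_cap: int | None = 500
    include_neighbors: bool = True
    cluster_distance: str = "correlation"
    cluster_linkage: str = "average"
    top_bc: int = 20
    top_hub: int = 9
    top_authority: int = 9
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.simulation is None:
            missing = [
                name
                for name in ("matrix_path", "samples_path", "annotations_path", "edges_path")
                if getattr(self, name) is None
            ]
            if missing:
                raise ValidationError(
                    f"config needs a simulation block or input paths; missing {missing}"
                )
            for name in ("matrix_path", "samples_path", "annotations_path", "edges_path"):
                if not Path(getattr(self, name)).exists():
                    raise ValidationError(f"{name} does not exist: {getattr(self, name)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        thresholds = raw.pop("thresholds", None)
        config = cls(**raw)
        if sim is not None:
            classes = [
                simulate.EffectClass(c["name"], c["n_genes"], tuple(c["log2_effects"]))
                for c in sim.pop("effect_classes", [])
            ]
            config.simulation = simulate.SimulationConfig(effect_classes=classes, **sim)
        if thresholds is not None:
            config.thresholds = de.DEThresholds(**thresholds)
        return config


@dataclass
class PipelineReport:
    params: dict
    summary: dict
    manifest: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(
            {"params": self.params, "summary": self.summary, "manifest": self.manifest},
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT, na_rep="NA")


def _config_echo(config: PipelineConfig) -> dict:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        return obj

    return encode(config)


def _simulated_inputs(config: PipelineConfig, outdir: Path):
    """Generate the full synthetic bundle and persist it.

    The motif network's node names are remapped onto gene identifiers
    (planted-effect genes first, in truth order) so that the network
    stage operates on the same namespace as the expression data.
    """
    sim = config.simulation
    study, truth = simulate.simulate_expression(sim)
    write_expression_study(study, outdir / "matrix.tsv", outdir / "samples.tsv")
    _write_tsv(truth.frame, outdir / "truth.tsv")

    planted = [
        simulate.PlantedCategory(f"planted_{name}", name, 0.9)
        for name in sorted({c.name for c in sim.effect_classes})
    ]
    catalog = simulate.simulate_annotations(
        truth.classes, n_categories=20, planted=planted, seed=sim.seed + 1
    )
    write_gmt(catalog, outdir / "annotations.gmt")

    # hub/authority block sized so its principal singular value dominates
    # the bridge clusters' (8*10 = 80 vs ~(0.6*10)^2 = 36): planted
    # hubs/authorities stay on top of the HITS ranking of the combined graph
    edges, roles = simulate.simulate_network(
        n_cluster_nodes=10, p_within=0.6, motif="both", seed=sim.seed + 2,
        n_hubs=8, n_authorities=10,
    )
    ordered_nodes = sorted(roles)
    frame = truth.frame
    planted_genes = list(frame.loc[frame["class"] != "null", "gene"])
    null_genes = list(frame.loc[frame["class"] == "null", "gene"])
    pool = planted_genes + null_genes
    if len(pool) < len(ordered_nodes):
        raise ValidationError("simulation has fewer genes than motif network nodes")
    mapping = {node: pool[i] for i, node in enumerate(ordered_nodes)}
    edges = edges.assign(
        source=edges["source"].map(mapping), target=edges["target"].map(mapping)
    )
    write_edge_table(edges, outdir / "edges.tsv")
    role_frame = pd.DataFrame(
        [{"node": n, "gene": mapping[n], "role": roles[n]} for n in ordered_nodes]
    )
    _write_tsv(role_frame, outdir / "network_truth.tsv")
    return study, catalog, edges


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute all stages in order, persisting every intermediate table."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    summary: dict = {}
    try:
        # ---- stage: inputs ------------------------------------------
        stage = "inputs"
        try:
            if config.simulation is not None:
                study, catalog, edges = _simulated_inputs(config, outdir)
            else:
                study = read_expression_study(config.matrix_path, config.samples_path)
                catalog = read_annotations(config.annotations_path, config.annotations_format)
                edges = read_edge_table(config.edges_path)
            log.info("loaded %d genes x %d samples", len(study.genes), len(study.samples))
            summary["n_genes"] = len(study.genes)
            summary["n_samples"] = len(study.samples)
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # ---- stage: qc + collapse -----------------------------------
        stage = "collapse"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                concordance, mean_r2 = replicate_concordance(study)
            if len(concordance):
                _write_tsv(concordance, outdir / "concordance.tsv")
                summary["mean_replicate_r2"] = mean_r2
            collapsed = collapse_replicates(study).floor(config.floor)
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # ---- stage: differential expression -------------------------
        stage = "de"
        try:
            contrasts = de.call_differential_genes(collapsed, config.thresholds, config.floor)
            _write_tsv(contrasts, outdir / "contrasts.tsv")
            sets = de.significant_sets(contrasts)
            sig_counts = {}
            for pair in de.PRIMARY_PAIRS:
                name = de.contrast_name(pair)
                for direction in ("up", "down"):
                    genes = sorted(sets[(name, direction)])
                    sig_counts[f"{name}_{direction}"] = len(genes)
                    _write_tsv(
                        pd.DataFrame({"gene": genes}), outdir / f"genes_{name}_{direction}.tsv"
                    )
            summary["significant"] = sig_counts
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # ---- stage: venn + cluster ----------------------------------
        stage = "sets"
        try:
            venn_counts = {}
            for direction in ("up", "down"):
                part = set_analysis.venn_partition(
                    sets[(de.contrast_name(de.PRIMARY_PAIRS[0]), direction)],
                    sets[(de.contrast_name(de.PRIMARY_PAIRS[1]), direction)],
                    sets[(de.contrast_name(de.PRIMARY_PAIRS[2]), direction)],
                    direction=direction,
                )
                _write_tsv(part.to_frame(), outdir / f"venn_{direction}.tsv")
                venn_counts[direction] = part.counts()
            summary["venn"] = venn_counts

            variable = set_analysis.select_variable_genes(contrasts)
            summary["n_variable_genes"] = len(variable)
            if len(variable) >= 2:
                clustering = set_analysis.hierarchical_cluster(
                    collapsed, variable, config.cluster_distance, config.cluster_linkage
                )
                _write_tsv(
                    pd.DataFrame({"gene": clustering.gene_order}),
                    outdir / "cluster_gene_order.tsv",
                )
                _write_tsv(
                    pd.DataFrame({"sample": clustering.sample_order}),
                    outdir / "cluster_sample_order.tsv",
                )
            else:
                log.warning("fewer than 2 variable genes; clustering skipped")
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # ---- stage: enrichment + augmentation -----------------------
        stage = "enrich"
        try:
            catalog_on_array = catalog.restrict(study.genes)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                enr = enrichment.hypergeometric_enrichment(variable, catalog_on_array)
            _write_tsv(enr, outdir / "enrichment.tsv")
            top = enrichment.top_categories(enr, config.q_max, config.min_k)
            summary["n_enriched_categories"] = len(top)
            augmented = enrichment.augment_gene_set(
                variable, top, catalog_on_array, cap=config.augment_cap
            )
            _write_tsv(augmented.provenance, outdir / "augmented_genes.tsv")
            summary["n_augmented_genes"] = len(augmented.genes)
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # ---- stage: network -----------------------------------------
        stage = "network"
        try:
            de_direction = {}
            primary_names = {de.contrast_name(p) for p in de.PRIMARY_PAIRS}
            for (name, direction), genes in sets.items():
                if name in primary_names:
                    for g in genes:
                        de_direction.setdefault(g, direction)
            if augmented.genes:
                net = network.build_network(
                    augmented.genes,
                    edges,
                    include_neighbors=config.include_neighbors,
                    seed_genes=variable,
                    de_direction=de_direction,
                )
            else:
                net = None
            if net is None or net.n_arcs == 0:
                log.warning("empty or arc-free network; centrality stage skipped")
                summary["network"] = {"n_nodes": 0 if net is None else net.n_nodes, "n_arcs": 0}
            else:
                bc = network.betweenness_centrality(net)
                hits, converged = network.hits_scores(net)
                if not converged:
                    log.warning("HITS did not converge within max_iter")
                table = network.rank_genes(net, bc, hits)
                _write_tsv(table, outdir / "centrality.tsv")
                net.to_pajek(outdir / "network.net")
                summary["network"] = {"n_nodes": net.n_nodes, "n_arcs": net.n_arcs}
                summary["top_bc"] = (
                    table.sort_values("bc_rank").head(config.top_bc)[["gene", "bc"]]
                    .to_dict("records")
                )
                summary["top_hub"] = (
                    table.sort_values("hub_rank").head(config.top_hub)[["gene", "hub"]]
                    .to_dict("records")
                )
                summary["top_authority"] = (
                    table.sort_values("authority_rank")
                    .head(config.top_authority)[["gene", "authority"]]
                    .to_dict("records")
                )
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # ---- report -------------------------------------------------
        manifest = {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name not in ("report.json", "run.log")
        }
        report = PipelineReport(params=_config_echo(config), summary=summary, manifest=manifest)
        (outdir / "report.json").write_text(report.to_json() + "\n")
        log.info("pipeline complete: %d files", len(manifest))
        return report
    finally:
        log.removeHandler(handler)
        handler.close()


def summarize_report(report_dir: str | Path) -> PipelineReport:
    """Re-read a report directory, verify checksums and summary counts."""
    outdir = Path(report_dir)
    report_path = outdir / "report.json"
    if not report_path.exists():
        raise IntegrityError(f"missing report.json in {outdir}")
    raw = json.loads(report_path.read_text())
    report = PipelineReport(params=raw["params"], summary=raw["summary"], manifest=raw["manifest"])

    for name, digest in report.manifest.items():
        path = outdir / name
        if not path.exists():
            raise IntegrityError(f"manifest file missing on disk: {name}")
        if _sha256(path) != digest:
            raise IntegrityError(f"checksum mismatch for {name}")

    # recompute headline counts from the persisted tables
    contrasts = pd.read_csv(outdir / "contrasts.tsv", sep="\t")
    sets = de.significant_sets(contrasts)
    for pair in de.PRIMARY_PAIRS:
        name = de.contrast_name(pair)
        for direction in ("up", "down"):
            stored = report.summary["significant"][f"{name}_{direction}"]
            actual = len(sets[(name, direction)])
            if stored != actual:
                raise IntegrityError(
                    f"significant count mismatch for {name}/{direction}: "
                    f"stored {stored}, recomputed {actual}"
                )
    return report
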