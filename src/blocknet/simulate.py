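"""Truth-known synthetic inputs: blocked factorial expression data with
planted condition effects, annotation catalogs with planted enriched
categories, and directed networks with planted bridge/hub/authority
nodes.

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
instance per operation, seeded explicitly; draws happen in a fixed,
documented order so outputs are bit-reproducible across runs and
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CONDITIONS, AnnotationCatalog, ExpressionStudy, make_edge_table


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass(frozen=True)
class EffectClass:
    """A named group of genes sharing one per-condition log2 effect vector.

    ``log2_effects`` follows the canonical condition order
    (medium, IgG, IL12, IgG_IL12); the medium entry must be 0.
    """

    name: str
    n_genes: int
    log2_effects: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.log2_effects) != len(CONDITIONS):
            raise ConfigError(f"class {self.name!r}: effect vector must have length 4")
        if self.log2_effects[0] != 0:
            raise ConfigError(f"class {self.name!r}: medium effect must be 0")
        if self.n_genes < 0:
            raise ConfigError(f"class {self.name!r}: negative gene count")


def default_effect_classes(n_per_class: int = 40, log2_fc: float = np.log2(3.0)) -> list[EffectClass]:
    """Archetype palette: combination-unique, singly-shared and
    triple-shared up/down classes around a null background."""
    e = log2_fc
    return [
        EffectClass("combo_up", n_per_class, (0.0, 0.0, 0.0, e)),
        EffectClass("igg_shared_up", n_per_class, (0.0, e, 0.0, e)),
        EffectClass("il12_shared_up", n_per_class, (0.0, 0.0, e, e)),
        EffectClass("all_up", n_per_class, (0.0, e, e, e)),
        EffectClass("combo_down", n_per_class, (0.0, 0.0, 0.0, -e)),
        EffectClass("igg_shared_down", n_per_class, (0.0, -e, 0.0, -e)),
    ]


@dataclass
class SimulationConfig:
    """Parameters of the blocked factorial generative model.

    intensity(g, d, c, r) = 2 ** (mu_g + beta_d + tau_{g,c} + eps) with
    mu_g ~ N(baseline_log2_mean, baseline_log2_sd), beta_d ~ N(0, donor_sd),
    tau the planted class effect and
    eps ~ N(0, sqrt(noise_sd**2 + replicate_sd**2)) drawn per array.
    """

    n_genes: int = 2000
    n_donors: int = 8
    n_replicates: int = 2
    baseline_log2_mean: float = 9.0
    baseline_log2_sd: float = 1.0
    donor_sd: float = 0.3
    noise_sd: float = 0.25
    replicate_sd: float = 0.1
    effect_classes: list[EffectClass] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_log2_sd", "donor_sd", "noise_sd", "replicate_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_genes < 1 or self.n_donors < 1 or self.n_replicates < 1:
            raise ConfigError("counts must be positive")
        planted = sum(c.n_genes for c in self.effect_classes)
        if planted > self.n_genes:
            raise ConfigError(
                f"effect classes claim {planted} genes but n_genes = {self.n_genes}"
            )


@dataclass
class SimulationTruth:
    """Per-gene ground truth: class label, true log2 effects, true fold
    changes vs medium and expected Venn regions at the 2-fold cutoff."""

    frame: pd.DataFrame

    @property
    def classes(self) -> dict[str, str]:
        return dict(zip(self.frame["gene"], self.frame["class"]))

    def genes_of_class(self, name: str) -> set[str]:
        return set(self.frame.loc[self.frame["class"] == name, "gene"])


def _expected_region(effects: np.ndarray, direction: str, fc_threshold: float = 2.0) -> str:
    """Venn region label (A=IgG, B=IL12, C=IgG_IL12) implied by true effects."""
    fc = 2.0**effects
    if direction == "up":
        member = fc > fc_threshold
    else:
        member = fc < 1.0 / fc_threshold
    return "".join(l for l, m in zip("ABC", member) if m)


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionStudy, SimulationTruth]:
    """Generate a blocked factorial study plus its ground truth.

    Draw order: (1) per-gene baselines, (2) per-donor block effects,
    (3) the full residual array (genes x donors x conditions x
    replicates).  Genes are assigned to effect classes sequentially,
    remainder labelled ``null``.
    """
    rng = np.random.default_rng(config.seed)
    width = max(5, len(str(config.n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    donors = [f"d{i:02d}" for i in range(1, config.n_donors + 1)]

    labels = ["null"] * config.n_genes
    tau = np.zeros((config.n_genes, len(CONDITIONS)))
    cursor = 0
    for cls in config.effect_classes:
        for g in range(cursor, cursor + cls.n_genes):
            labels[g] = cls.name
            tau[g] = cls.log2_effects
        cursor += cls.n_genes

    mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    beta = rng.normal(0.0, config.donor_sd, config.n_donors)
    eps_sd = float(np.sqrt(config.noise_sd**2 + config.replicate_sd**2))
    eps = rng.normal(
        0.0,
        eps_sd,
        size=(config.n_genes, config.n_donors, len(CONDITIONS), config.n_replicates),
    )
    log2_y = (
        mu[:, None, None, None]
        + beta[None, :, None, None]
        + tau[:, None, :, None]
        + eps
    )
    intensities = 2.0**log2_y

    samples, columns, rows = [], [], []
    for d_i, donor in enumerate(donors):
        for c_i, cond in enumerate(CONDITIONS):
            for rep in range(1, config.n_replicates + 1):
                sid = f"{donor}_{cond}_r{rep}"
                samples.append(sid)
                columns.append(intensities[:, d_i, c_i, rep - 1])
                rows.append(
                    {"sample_id": sid, "donor": donor, "condition": cond, "replicate": rep}
                )
    study = ExpressionStudy(
        genes=genes,
        samples=samples,
        intensities=np.column_stack(columns),
        design=pd.DataFrame(rows).set_index("sample_id"),
    )

    truth = pd.DataFrame({"gene": genes, "class": labels})
    for j, cond in enumerate(CONDITIONS):
        if cond == "medium":
            continue
        truth[f"effect_{cond}"] = tau[:, j]
        truth[f"fc_{cond}"] = 2.0 ** tau[:, j]
    truth["expected_up_region"] = [
        _expected_region(tau[g, 1:], "up") for g in range(config.n_genes)
    ]
    truth["expected_down_region"] = [
        _expected_region(tau[g, 1:], "down") for g in range(config.n_genes)
    ]
    return study, SimulationTruth(frame=truth)


# ---------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedCategory:
    """Category drawing ``fraction`` of its members from one truth class."""

    name: str
    class_name: str
    fraction: float
    size: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigError(f"fraction must be in [0, 1], got {self.fraction}")


def simulate_annotations(
    classes: Mapping[str, str],
    n_categories: int,
    planted: list[PlantedCategory],
    seed: int,
    category_size: int = 25,
) -> AnnotationCatalog:
    """Random annotation catalog with planted enriched categories.

    ``classes`` maps gene -> truth class.  Background categories sample
    ``category_size`` genes uniformly without replacement; each planted
    category draws ``round(fraction * size)`` members from its class and
    the rest uniformly from outside the class.  Draw order: background
    categories first (in index order), then planted categories (in list
    order).
    """
    rng = np.random.default_rng(seed)
    genes = sorted(classes)
    universe = set(genes)
    known_classes = set(classes.values())
    for p in planted:
        if p.class_name not in known_classes:
            raise ConfigError(f"unknown truth class {p.class_name!r}")

    categories: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(1, n_categories + 1):
        name = f"bg_cat_{i:03d}"
        size = min(category_size, len(genes))
        categories[name] = set(rng.choice(genes, size=size, replace=False))
        descriptions[name] = "background"

    for p in planted:
        class_genes = sorted(g for g, c in classes.items() if c == p.class_name)
        other_genes = sorted(set(genes) - set(class_genes))
        size = p.size if p.size is not None else category_size
        n_from_class = min(int(round(p.fraction * size)), len(class_genes))
        members = set(rng.choice(class_genes, size=n_from_class, replace=False))
        n_rest = min(size - n_from_class, len(other_genes))
        if n_rest > 0:
            members |= set(rng.choice(other_genes, size=n_rest, replace=False))
        categories[p.name] = members
        descriptions[p.name] = f"planted:{p.class_name}"

    return AnnotationCatalog(categories=categories, descriptions=descriptions, universe=universe)


# ---------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------


def simulate_network(
    n_cluster_nodes: int,
    p_within: float,
    motif: str,
    seed: int,
    n_hubs: int = 2,
    n_authorities: int = 3,
    n_background: int | None = None,
    p_background: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Directed network with planted bridge and/or hub/authority motifs.

    ``bridge``: two dense random directed clusters joined only through a
    designated bridge node that has arcs both ways to every cluster
    node, so the bridge dominates betweenness by construction.
    ``hub_authority``: designated hubs arc to every designated authority
    (dense bipartite block) over a sparse random background.
    ``both``: disjoint union of the two motifs.

    Returns the edge table and a node -> role map
    (bridge/cluster1/cluster2/hub/authority/background).
    """
    if n_cluster_nodes < 3:
        raise ConfigError("n_cluster_nodes must be >= 3")
    if not 0.0 < p_within <= 1.0:
        raise ConfigError("p_within must be in (0, 1]")
    if motif not in ("bridge", "hub_authority", "both"):
        raise ConfigError(f"unknown motif {motif!r}")
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    truth: dict[str, str] = {}

    if motif in ("bridge", "both"):
        c1 = [f"c1_{i:02d}" for i in range(n_cluster_nodes)]
        c2 = [f"c2_{i:02d}" for i in range(n_cluster_nodes)]
        for label, cluster in (("cluster1", c1), ("cluster2", c2)):
            for u in cluster:
                truth[u] = label
            for u in cluster:
                for v in cluster:
                    if u != v and rng.random() < p_within:
                        rows.append((u, v, 1.0, "cluster", 1))
        bridge = "bridge"
        truth[bridge] = "bridge"
        for u in c1 + c2:
            rows.append((bridge, u, 1.0, "bridge", 1))
            rows.append((u, bridge, 1.0, "bridge", 1))

    if motif in ("hub_authority", "both"):
        hubs = [f"h_{i:02d}" for i in range(n_hubs)]
        auths = [f"a_{i:02d}" for i in range(n_authorities)]
        for u in hubs:
            truth[u] = "hub"
        for v in auths:
            truth[v] = "authority"
        for u in hubs:
            for v in auths:
                rows.append((u, v, 1.0, "hub_auth", 1))
        n_bg = n_cluster_nodes if n_background is None else n_background
        bg = [f"bg_{i:02d}" for i in range(n_bg)]
        for u in bg:
            truth[u] = "background"
        for u in bg:
            for v in bg:
                if u != v and rng.random() < p_background:
                    rows.append((u, v, 1.0, "background", 1))

    return make_edge_table(rows), truth
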