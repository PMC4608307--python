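"""Venn partitioning of up/down gene sets and hierarchical clustering of
differentially expressed genes."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import ExpressionStudy, ValidationError

#: The 7 non-empty intersection regions of three sets A, B, C.
REGIONS: tuple[str, ...] = ("A", "B", "C", "AB", "AC", "BC", "ABC")


@dataclass
class VennPartition:
    """Disjoint membership of three gene sets' 7 intersection regions.

    Region keys name the sets an element belongs to: ``"A"`` is A-only,
    ``"AB"`` is (A and B)-only, ``"ABC"`` is the triple intersection.
    """

    regions: dict[str, set[str]]
    labels: tuple[str, str, str]
    direction: str = ""

    def counts(self) -> dict[str, int]:
        return {r: len(self.regions[r]) for r in REGIONS}

    def set_total(self, which: str) -> int:
        """Cardinality of the original input set A, B or C."""
        return sum(len(g) for r, g in self.regions.items() if which in r)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": r, "n": len(self.regions[r]), "genes": ",".join(sorted(self.regions[r]))}
            for r in REGIONS
        ]
        return pd.DataFrame(rows)


def venn_partition(
    set_a: set[str],
    set_b: set[str],
    set_c: set[str],
    labels: tuple[str, str, str] = ("IgG", "IL12", "IgG_IL12"),
    direction: str = "",
) -> VennPartition:
    """Exact set algebra over the 7 regions of three sets."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    regions = {
        "A": a - b - c,
        "B": b - a - c,
        "C": c - a - b,
        "AB": (a & b) - c,
        "AC": (a & c) - b,
        "BC": (b & c) - a,
        "ABC": a & b & c,
    }
    return VennPartition(regions=regions, labels=labels, direction=direction)


def select_variable_genes(table: pd.DataFrame) -> set[str]:
    """Genes passing the full triple filter in any primary comparison,
    either direction."""
    mask = table["primary"] & table["significant"]
    return set(table.loc[mask, "gene"])


@dataclass
class ClusterResult:
    """Leaf orders and merge trees of the two-axis agglomerative clustering."""

    gene_order: list[str]
    sample_order: list[str]
    gene_linkage: np.ndarray
    sample_linkage: np.ndarray
    centered: pd.DataFrame  # mean-centered display matrix (genes x samples)


def _correlation_distance(matrix: np.ndarray) -> np.ndarray:
    """1 - Pearson between rows; zero-variance rows get the maximal 2.0."""
    sd = matrix.std(axis=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance rows; correlation distance set to 2.0")
    safe = matrix.copy()
    safe[zero] = np.arange(matrix.shape[1])  # placeholder, overwritten below
    corr = np.corrcoef(safe)
    dist = 1.0 - corr
    dist[zero, :] = 2.0
    dist[:, zero] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    return (dist + dist.T) / 2.0


def _linkage(matrix: np.ndarray, distance: str, linkage: str) -> np.ndarray:
    if matrix.shape[0] == 1:
        return np.empty((0, 4))
    if distance == "correlation":
        dist = _correlation_distance(matrix)
        condensed = squareform(dist, checks=False)
    elif distance == "euclidean":
        from scipy.spatial.distance import pdist

        condensed = pdist(matrix, metric="euclidean")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    if linkage not in ("average", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    return hierarchy.linkage(condensed, method=linkage)


def hierarchical_cluster(
    study: ExpressionStudy,
    genes: set[str] | list[str],
    distance: str = "correlation",
    linkage: str = "average",
) -> ClusterResult:
    """Cluster genes and samples over the selected gene rows.

    Rows are mean-centered across samples before distances are computed.
    Output is deterministic for a fixed input: scipy's linkage tie
    handling plus input-order leaves.
    """
    gene_list = [g for g in study.genes if g in set(genes)]
    if len(gene_list) < 2:
        raise ValidationError("need at least 2 genes to cluster")
    if len(study.samples) < 2:
        raise ValidationError("need at least 2 samples to cluster")
    idx = [study.genes.index(g) for g in gene_list]
    matrix = study.intensities[idx, :].astype(float)
    centered = matrix - matrix.mean(axis=1, keepdims=True)

    gene_link = _linkage(centered, distance, linkage)
    sample_link = _linkage(centered.T, distance, linkage)
    gene_order = [gene_list[i] for i in hierarchy.leaves_list(gene_link)]
    sample_order = [study.samples[i] for i in hierarchy.leaves_list(sample_link)]
    return ClusterResult(
        gene_order=gene_order,
        sample_order=sample_order,
        gene_linkage=gene_link,
        sample_linkage=sample_link,
        centered=pd.DataFrame(centered, index=gene_list, columns=study.samples),
    )
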