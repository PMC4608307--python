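"""Hypergeometric category overrepresentation and enrichment-driven
augmentation of a seed gene set."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnotationCatalog

ENRICHMENT_COLUMNS = ["category", "description", "k", "K", "n", "N", "p", "q", "ratio"]


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def hypergeometric_enrichment(query: set[str], catalog: AnnotationCatalog) -> pd.DataFrame:
    """Upper-tail hypergeometric test of every category against the query.

    p = P(X >= k) for X ~ Hypergeom(N, K, n) with N the universe size,
    K the category size in the universe, n the query size after
    restriction to the universe, k the observed overlap.  Only
    categories with k >= 1 are tested; q is BH-adjusted across the
    tested categories.
    """
    universe = catalog.universe
    n_query = query & universe
    if not n_query:
        warnings.warn("query is empty after restriction to the annotation universe")
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    N = len(universe)
    n = len(n_query)
    rows = []
    for name in sorted(catalog.categories):
        members = catalog.categories[name] & universe
        K = len(members)
        k = len(n_query & members)
        if k < 1:
            continue
        # P(X >= k) == sf(k - 1)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        rows.append(
            {
                "category": name,
                "description": catalog.descriptions.get(name, ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": p,
                "ratio": (k / n) / (K / N),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = benjamini_hochberg(table["p"].to_numpy())
    else:
        table["q"] = []
    return table[ENRICHMENT_COLUMNS]


def top_categories(table: pd.DataFrame, q_max: float = 0.05, min_k: int = 2) -> list[str]:
    """Categories with q < q_max and k >= min_k, ordered by ascending q,
    then descending k, then category id."""
    if not len(table):
        return []
    sel = table.loc[(table["q"] < q_max) & (table["k"] >= min_k)].copy()
    sel = sel.sort_values(["q", "k", "category"], ascending=[True, False, True], kind="stable")
    return list(sel["category"])


@dataclass
class AugmentResult:
    """Seed union category members, with per-gene provenance."""

    genes: set[str]
    provenance: pd.DataFrame = field(repr=False)  # gene, origin, category


def augment_gene_set(
    seed_genes: set[str],
    categories: list[str],
    catalog: AnnotationCatalog,
    cap: int | None = None,
) -> AugmentResult:
    """Union the seed with the members of the listed categories.

    Genes added beyond ``cap`` are truncated in category order, then by
    gene id within a category.  Provenance records, per gene, whether it
    came from the seed or via which category.
    """
    unknown = [c for c in categories if c not in catalog.categories]
    if unknown:
        raise KeyError(f"categories not in catalog: {unknown}")
    rows = [{"gene": g, "origin": "seed", "category": ""} for g in sorted(seed_genes)]
    result = set(seed_genes)
    added = 0
    for cat in categories:
        for gene in sorted(catalog.categories[cat]):
            if gene in result:
                continue
            if cap is not None and added >= cap:
                break
            result.add(gene)
            added += 1
            rows.append({"gene": gene, "origin": "augmented", "category": cat})
        if cap is not None and added >= cap:
            break
    return AugmentResult(genes=result, provenance=pd.DataFrame(rows, columns=["gene", "origin", "category"]))
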