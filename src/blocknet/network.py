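"""Directed functional-network assembly, betweenness centrality, HITS
hub/authority scoring and tie-broken rank tables."""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import ValidationError, write_pajek


@dataclass
class FunctionalNetwork:
    """Directed weighted graph over genes.

    At most one arc per ordered node pair (parallel input rows are
    weight-aggregated); no self-loops.  Node attributes record seed
    membership and differential-expression direction when supplied.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_arcs(self) -> int:
        return self.graph.number_of_edges()

    def arcs(self) -> list[tuple[str, str, float]]:
        return [(s, t, d["weight"]) for s, t, d in sorted(self.graph.edges(data=True))]

    def to_pajek(self, path) -> None:
        write_pajek(self.nodes, self.arcs(), path)


def build_network(
    gene_set: set[str],
    edges: pd.DataFrame,
    include_neighbors: bool = False,
    seed_genes: set[str] | None = None,
    de_direction: dict[str, str] | None = None,
) -> FunctionalNetwork:
    """Induce the directed network on ``gene_set`` from an edge table.

    Undirected rows expand to two opposing arcs; parallel arcs are
    aggregated by weight sum, contributing edge types recorded.  With
    ``include_neighbors`` the node set grows by first neighbors of the
    requested genes.  Requested genes with no arcs are retained as
    isolated nodes.
    """
    gene_set = set(gene_set)
    if include_neighbors:
        touching = edges["source"].isin(gene_set) | edges["target"].isin(gene_set)
        nodes = gene_set | set(edges.loc[touching, "source"]) | set(edges.loc[touching, "target"])
    else:
        nodes = gene_set
    if not nodes:
        raise ValidationError("empty node set; nothing to build")

    graph = nx.DiGraph()
    graph.add_nodes_from(sorted(nodes))
    keep = edges["source"].isin(nodes) & edges["target"].isin(nodes)
    for row in edges.loc[keep].itertuples(index=False):
        pairs = [(row.source, row.target)]
        if not row.directed:
            pairs.append((row.target, row.source))
        for s, t in pairs:
            if graph.has_edge(s, t):
                graph[s][t]["weight"] += float(row.weight)
                graph[s][t]["edge_types"] = sorted(
                    set(graph[s][t]["edge_types"]) | {row.edge_type}
                )
            else:
                graph.add_edge(s, t, weight=float(row.weight), edge_types=[row.edge_type])

    seed_genes = set(seed_genes) if seed_genes is not None else set(gene_set)
    de_direction = de_direction or {}
    for n in graph.nodes:
        graph.nodes[n]["in_seed"] = n in seed_genes
        graph.nodes[n]["de_direction"] = de_direction.get(n, "none")
    return FunctionalNetwork(graph=graph)


def betweenness_centrality(net: FunctionalNetwork) -> dict[str, float]:
    """Normalized betweenness centrality on the directed graph.

    Brandes' accumulation over unweighted (hop-count) shortest paths:
    raw BC(v) = sum over ordered pairs s != v != t with sigma_st > 0 of
    sigma_st(v) / sigma_st, then divided by (n-1)(n-2) for n >= 3
    (all zeros for n < 3).  Disconnected pairs simply contribute
    nothing.
    """
    graph = net.graph
    nodes = list(graph.nodes)
    n = len(nodes)
    bc = dict.fromkeys(nodes, 0.0)
    if n < 3:
        return bc
    adjacency = {v: list(graph.successors(v)) for v in nodes}
    for s in nodes:
        # single-source BFS with path counting
        sigma = dict.fromkeys(nodes, 0.0)
        dist = dict.fromkeys(nodes, -1)
        preds: dict[str, list[str]] = {v: [] for v in nodes}
        sigma[s] = 1.0
        dist[s] = 0
        order: list[str] = []
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in adjacency[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        # back-propagate dependencies
        delta = dict.fromkeys(nodes, 0.0)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    scale = 1.0 / ((n - 1) * (n - 2))
    return {v: bc[v] * scale for v in nodes}


def hits_scores(
    net: FunctionalNetwork,
    tol: float = 1e-8,
    max_iter: int = 1000,
    weighted: bool = False,
) -> tuple[dict[str, tuple[float, float]], bool]:
    """HITS hub/authority scores by power iteration.

    From a uniform positive start: a <- A^T h, h <- A a, each
    L2-normalized per iteration, where A is the (by default unweighted)
    adjacency matrix.  Stops when the max absolute change of both
    vectors falls below ``tol`` or after ``max_iter`` iterations.
    Returns (node -> (hub, authority), converged).  Nodes incident to no
    arc score 0 in both.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    graph = net.graph
    if graph.number_of_edges() == 0:
        raise ValidationError("HITS undefined on an arc-free network")
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for s, t, d in graph.edges(data=True):
        A[index[s], index[t]] = d["weight"] if weighted else 1.0

    h = np.ones(n) / np.sqrt(n)
    a = np.ones(n) / np.sqrt(n)
    converged = False
    for _ in range(max_iter):
        a_new = A.T @ h
        norm = np.linalg.norm(a_new)
        if norm > 0:
            a_new /= norm
        h_new = A @ a_new
        norm = np.linalg.norm(h_new)
        if norm > 0:
            h_new /= norm
        if max(np.max(np.abs(a_new - a)), np.max(np.abs(h_new - h))) < tol:
            a, h = a_new, h_new
            converged = True
            break
        a, h = a_new, h_new
    return {v: (float(h[index[v]]), float(a[index[v]])) for v in nodes}, converged


def rank_genes(
    net: FunctionalNetwork,
    bc: dict[str, float],
    hits: dict[str, tuple[float, float]],
) -> pd.DataFrame:
    """Build the centrality table with three independent 1-based ranks.

    Each rank orders descending by score with ties broken by ascending
    gene identifier; seed/DE provenance columns come from the node
    attributes set at build time.
    """
    nodes = net.nodes
    for name, mapping in (("bc", bc), ("hits", hits)):
        missing = [v for v in nodes if v not in mapping]
        if missing:
            raise ValidationError(f"{name} score map missing nodes: {missing}")
    table = pd.DataFrame(
        {
            "gene": nodes,
            "bc": [bc[v] for v in nodes],
            "hub": [hits[v][0] for v in nodes],
            "authority": [hits[v][1] for v in nodes],
            "in_seed": [bool(net.graph.nodes[v].get("in_seed", False)) for v in nodes],
            "de_direction": [net.graph.nodes[v].get("de_direction", "none") for v in nodes],
        }
    )
    for col in ("bc", "hub", "authority"):
        order = sorted(range(len(table)), key=lambda i: (-table[col].iat[i], table["gene"].iat[i]))
        ranks = np.empty(len(table), dtype=int)
        for r, i in enumerate(order, start=1):
            ranks[i] = r
        table[f"{col}_rank"] = ranks
    return table[
        [
            "gene",
            "bc",
            "bc_rank",
            "hub",
            "hub_rank",
            "authority",
            "authority_rank",
            "in_seed",
            "de_direction",
        ]
    ]
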