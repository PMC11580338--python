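"""Network analysis at three granularity levels.

Global level: the node set of a phenotype's co-occurrence network.
Community level: Leiden community detection under the Constant Potts Model
(CPM) objective Q = Σ_c [e_c − γ·n_c(n_c−1)/2], with the resolution γ
defaulting to the first quartile of node degree divided by (n − 1).
Key-element level: hub (eigenvector-type) centrality and shortest-path
betweenness, with the top-k species of each reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CommunityPartition",
    "CentralityReport",
    "global_species",
    "default_resolution",
    "cpm_quality",
    "leiden_cpm",
    "hub_scores",
    "betweenness",
    "top_k",
    "centrality_report",
]


@dataclass
class CommunityPartition:
    """A node → cluster assignment with its CPM quality."""

    assignment: dict[str, int]  # cluster ids contiguous from 1
    gamma: float
    quality: float
    seed: int

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, []).append(node)
        return {cid: sorted(nodes) for cid, nodes in sorted(out.items())}

    def summary(self) -> pd.DataFrame:
        """Cluster-size table ('Cluster No.' / 'Total Species')."""
        records = [
            {"cluster_id": cid, "n_species": len(nodes)}
            for cid, nodes in self.clusters().items()
        ]
        return pd.DataFrame(records, columns=["cluster_id", "n_species"])


@dataclass
class CentralityReport:
    """Hub and betweenness scores plus the top-k lists of each."""

    hub: dict[str, float]
    betweenness: dict[str, float]
    top_hub: list[str]
    top_betweenness: list[str]


def global_species(network: nx.Graph) -> set[str]:
    """All species captured by the network (the node set)."""
    return set(network.nodes())


def default_resolution(
    network: nx.Graph, quantile: float = 0.25, denominator: str = "n-1"
) -> float:
    """Degree-quartile resolution heuristic for CPM.

    γ = (first quartile of node degree, linear-interpolation quantile)
    divided by (n − 1) by default; on an unweighted graph node strength is
    the degree.  ``denominator='n'`` divides by the node count instead.
    """
    n = network.number_of_nodes()
    if n < 2:
        raise ValueError("resolution heuristic needs at least 2 nodes")
    degrees = np.array([d for _, d in network.degree()], dtype=float)
    q = float(np.quantile(degrees, quantile))
    denom = n - 1 if denominator == "n-1" else n
    return q / denom


def cpm_quality(network: nx.Graph, assignment: Mapping[str, int], gamma: float) -> float:
    """CPM objective Q = Σ_c [e_c − γ·n_c(n_c−1)/2] (edge-count form)."""
    sizes: dict[int, int] = {}
    for node in network.nodes():
        cid = assignment[node]
        sizes[cid] = sizes.get(cid, 0) + 1
    intra: dict[int, int] = {}
    for a, b in network.edges():
        if assignment[a] == assignment[b]:
            cid = assignment[a]
            intra[cid] = intra.get(cid, 0) + 1
    q = 0.0
    for cid, n_c in sizes.items():
        q += intra.get(cid, 0) - gamma * n_c * (n_c - 1) / 2
    return q


def leiden_cpm(
    network: nx.Graph,
    gamma: float | None = None,
    seed: int = 42,
    n_iterations: int = 10,
    n_restarts: int = 30,
) -> CommunityPartition:
    """Leiden community detection under the CPM objective.

    Leiden is a stochastic local optimizer, so the procedure is restarted
    from ``n_restarts`` seeds derived deterministically from ``seed`` and
    the best-quality partition is kept (ties go to the earliest restart).
    Deterministic given the seed.  Cluster ids are relabeled contiguously
    from 1 in order of first appearance over the sorted node list, and the
    reported quality is an independent recomputation of the CPM objective.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty network")
    if gamma is None:
        gamma = default_resolution(network)
    nodes = sorted(network.nodes())
    index = {name: i for i, name in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in network.edges()]
    graph = ig.Graph(n=len(nodes), edges=edges, directed=False)
    best_membership = None
    best_quality = float("-inf")
    for restart in range(max(1, n_restarts)):
        partition = leidenalg.find_partition(
            graph,
            leidenalg.CPMVertexPartition,
            resolution_parameter=gamma,
            n_iterations=n_iterations,
            seed=(seed + restart) % 2**31,
        )
        quality = partition.quality()
        if quality > best_quality + 1e-12:
            best_quality = quality
            best_membership = list(partition.membership)
    relabel: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for name in nodes:
        raw = best_membership[index[name]]
        if raw not in relabel:
            relabel[raw] = len(relabel) + 1
        assignment[name] = relabel[raw]
    quality = cpm_quality(network, assignment, gamma)
    return CommunityPartition(assignment=assignment, gamma=gamma, quality=quality, seed=seed)


def _component_principal(adj: np.ndarray, tol: float = 1e-10, max_iter: int = 100_000):
    """Perron vector and spectral radius of a connected adjacency matrix.

    Power iteration on A + I: the shift removes the ±λ ambiguity of bipartite
    components while preserving the Perron vector.
    """
    n = adj.shape[0]
    shifted = adj + np.eye(n)
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        y = shifted @ x
        norm = np.linalg.norm(y)
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    lam = float(x @ (adj @ x))  # Rayleigh quotient on the unshifted matrix
    return np.abs(x), lam


def hub_scores(network: nx.Graph) -> dict[str, float]:
    """Hub centrality, max-normalized to 1 over the whole graph.

    On an undirected graph the hub score is the principal eigenvector of the
    adjacency matrix.  Disconnected graphs are scored per connected
    component (max-normalized within the component, weighted by the
    component's spectral radius) and then globally max-normalized, so nodes
    outside the dominant component still receive comparable scores.
    """
    if network.number_of_nodes() == 0:
        return {}
    raw: dict[str, float] = {}
    lam_max = 0.0
    component_scores: list[tuple[list[str], np.ndarray, float]] = []
    for comp in nx.connected_components(network):
        nodes = sorted(comp)
        if len(nodes) == 1:
            component_scores.append((nodes, np.array([1.0]), 0.0))
            continue
        adj = nx.to_numpy_array(network, nodelist=nodes)
        vec, lam = _component_principal(adj)
        component_scores.append((nodes, vec / vec.max(), lam))
        lam_max = max(lam_max, lam)
    for nodes, vec, lam in component_scores:
        weight = lam / lam_max if lam_max > 0 else 1.0
        for name, score in zip(nodes, vec):
            raw[name] = float(score * weight)
    peak = max(raw.values())
    return {name: score / peak for name, score in raw.items()}


def betweenness(network: nx.Graph) -> dict[str, float]:
    """Unnormalized shortest-path betweenness (each unordered pair counted once)."""
    return {
        node: float(score)
        for node, score in nx.betweenness_centrality(network, normalized=False).items()
    }


def top_k(scores: Mapping[str, float], k: int = 5) -> list[str]:
    """Top-k nodes by descending score; ties broken by ascending name."""
    ordered = sorted(scores.items(), key=lambda item: (-item[1], item[0]))
    return [name for name, _ in ordered[:k]]


def centrality_report(network: nx.Graph, k: int = 5) -> CentralityReport:
    hub = hub_scores(network)
    btw = betweenness(network)
    return CentralityReport(
        hub=hub,
        betweenness=btw,
        top_hub=top_k(hub, k),
        top_betweenness=top_k(btw, k),
    )
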