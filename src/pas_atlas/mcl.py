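"""Markov clustering of the similarity network.

Classic MCL on the column-stochastic flow matrix of the network:
alternate expansion (matrix squaring, i.e. two random-walk steps) with
inflation (elementwise power and column renormalization, which sharpens
flow toward attractors), pruning tiny entries between rounds.  Inflation
1.4 — the granularity used for the domain-family atlas — is the default.
Clusters are numbered 1..K by decreasing size, so cluster 1 is always the
largest family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .similarity import SimilarityGraph


@dataclass(frozen=True)
class MclParams:
    """Tunables of the MCL iteration.

    inflation
        Elementwise exponent r > 1; larger values give finer clusters.
    expansion_power
        Number of random-walk steps per round (2 = matrix squaring).
    prune_threshold
        Entries below this probability are dropped after inflation (the
        column maximum is always kept), then columns are renormalized.
    convergence_tol
        Iteration stops when the largest absolute entry change between
        successive rounds falls below this.
    """

    inflation: float = 1.4
    expansion_power: int = 2
    prune_threshold: float = 1e-5
    max_iterations: int = 200
    convergence_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if not 0 <= self.prune_threshold <= 0.01:
            raise ValueError("prune_threshold must be in [0, 0.01]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.expansion_power < 2:
            raise ValueError("expansion_power must be >= 2")


@dataclass
class ClusterSet:
    """A size-ordered partition of the network's nodes.

    ``clusters[k]`` holds the members of cluster number ``k+1``; sizes are
    non-increasing.  ``membership`` maps node id -> 1-based cluster number.
    """

    clusters: list[frozenset[str]]
    membership: dict[str, int]

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_sequences(self) -> int:
        return sum(self.sizes)

    def members(self, number: int) -> frozenset[str]:
        if not 1 <= number <= len(self.clusters):
            raise KeyError(f"no cluster numbered {number}")
        return self.clusters[number - 1]


def _stochastic_matrix(graph: SimilarityGraph, nodes: Sequence[str]) -> np.ndarray:
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for (u, v), w in graph.edges.items():
        if w < 0:
            raise ValueError("negative edge weight in similarity graph")
        i, j = index[u], index[v]
        a[i, j] = w
        a[j, i] = w
    # self-loops: maximum incident weight stabilizes attractors; isolated
    # nodes get a unit loop so their column is well defined.
    for i in range(n):
        m = a[i].max()
        a[i, i] = m if m > 0 else 1.0
    return a / a.sum(axis=0, keepdims=True)


def _inflate_and_prune(m: np.ndarray, params: MclParams) -> np.ndarray:
    m = np.power(m, params.inflation)
    if params.prune_threshold > 0:
        keep_max = m.max(axis=0, keepdims=True)
        m[(m < params.prune_threshold) & (m < keep_max)] = 0.0
    colsums = m.sum(axis=0, keepdims=True)
    return m / colsums


def mcl_iterations(matrix: np.ndarray, params: MclParams = MclParams()) -> Iterator[np.ndarray]:
    """Yield the column-stochastic matrix after each expansion+inflation
    round, stopping at convergence or ``max_iterations``."""
    m = matrix
    for _ in range(params.max_iterations):
        expanded = np.linalg.matrix_power(m, params.expansion_power)
        new = _inflate_and_prune(expanded, params)
        yield new
        if np.abs(new - m).max() < params.convergence_tol:
            return
        m = new


def _clusters_from_limit(m: np.ndarray, nodes: Sequence[str]) -> list[set[str]]:
    n = len(nodes)
    tol = 1e-7
    attractors = [i for i in range(n) if m[i, i] > tol]
    if not attractors:
        attractors = [int(np.argmax(m[:, j])) for j in range(n)]
        attractors = sorted(set(attractors))
    # attractor systems: merge attractor rows with overlapping support
    parent = list(range(len(attractors)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent[find(x)] = find(y)

    supports = [set(np.nonzero(m[i] > tol)[0]) for i in attractors]
    for a in range(len(attractors)):
        for b in range(a + 1, len(attractors)):
            if supports[a] & supports[b]:
                union(a, b)
    systems: dict[int, set[int]] = {}
    for k in range(len(attractors)):
        systems.setdefault(find(k), set()).update(supports[k])
    system_rows: dict[int, list[int]] = {}
    for k, i in enumerate(attractors):
        system_rows.setdefault(find(k), []).append(i)

    # resolve overlaps / stragglers: each node goes to the system with the
    # largest flow into it; ties to the system with the smallest member set
    order = sorted(systems)
    assignment: dict[int, int] = {}
    for j in range(n):
        best = None
        for key in order:
            flow = max(m[i, j] for i in system_rows[key])
            in_support = j in systems[key]
            cand = (1 if in_support else 0, flow)
            if best is None or cand > best[0]:
                best = (cand, key)
        assignment[j] = best[1]
    out: dict[int, set[str]] = {}
    for j, key in assignment.items():
        out.setdefault(key, set()).add(nodes[j])
    return list(out.values())


def mcl_cluster(graph: SimilarityGraph, params: MclParams = MclParams()) -> ClusterSet:
    """Cluster the similarity network with MCL and number clusters by size.

    Raises ``ValueError`` on an empty graph or negative edge weights.
    Every node ends up in exactly one cluster; nodes with no surviving
    flow toward any attractor are assigned to the attractor system with
    the largest flow into them (ties resolved deterministically).
    """
    if graph.n_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    nodes = sorted(graph.nodes)
    m = _stochastic_matrix(graph, nodes)
    for m in mcl_iterations(m, params):
        pass
    raw = _clusters_from_limit(m, nodes)
    return number_clusters(raw)


def number_clusters(raw_clusters: Iterable[Iterable[str]]) -> ClusterSet:
    """Order a raw partition by decreasing size and number from 1.

    Ties in size are broken by the lexicographically smallest member id.
    """
    groups = [frozenset(c) for c in raw_clusters if len(frozenset(c)) > 0]
    seen: set[str] = set()
    for g in groups:
        if seen & g:
            raise ValueError("clusters overlap; not a partition")
        seen |= g
    groups.sort(key=lambda g: (-len(g), min(g)))
    membership = {node: k + 1 for k, g in enumerate(groups) for node in g}
    return ClusterSet(clusters=groups, membership=membership)


def cluster_distance(a: int, b: int, clusters: ClusterSet, graph: SimilarityGraph,
                     directed_hits: bool = False) -> float:
    """Inter-cluster distance: cross-edge count / (|A| * |B|).

    With ``directed_hits`` each undirected edge counts as two hits
    (mirroring search tools that report both directions), so the value
    may exceed 1.
    """
    if a == b:
        raise ValueError("cluster_distance is defined for distinct clusters")
    group_a = set(clusters.members(a))
    group_b = set(clusters.members(b))
    hits = graph.count_cross_edges(group_a, group_b)
    if directed_hits:
        hits *= 2
    return hits / (len(group_a) * len(group_b))


def distance_matrix(clusters: ClusterSet, graph: SimilarityGraph,
                    directed_hits: bool = False) -> pd.DataFrame:
    """Symmetric table of pairwise inter-cluster distances (diagonal NaN)."""
    k = clusters.n_clusters
    numbers = list(range(1, k + 1))
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            d = cluster_distance(numbers[i], numbers[j], clusters, graph, directed_hits)
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=numbers, columns=numbers)


@dataclass(frozen=True)
class ClusterSummary:
    """Size table plus coverage of the large clusters."""

    table: pd.DataFrame
    min_size: int
    n_qualifying: int
    coverage: float


def cluster_summary(clusters: ClusterSet, min_size: int = 100) -> ClusterSummary:
    """Per-cluster sizes and the fraction of all sequences that live in
    clusters of at least ``min_size`` members."""
    sizes = clusters.sizes
    table = pd.DataFrame({"cluster": range(1, len(sizes) + 1), "size": sizes})
    table["qualifying"] = table["size"] >= min_size
    total = int(table["size"].sum())
    covered = int(table.loc[table["qualifying"], "size"].sum())
    coverage = covered / total if total else 0.0
    return ClusterSummary(table=table, min_size=min_size,
                          n_qualifying=int(table["qualifying"].sum()),
                          coverage=coverage)
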