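"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the alignment oracle
is a recursive memoized affine-gap DP written from the recurrence, and
the component oracle is a plain union-find.
"""

from functools import lru_cache

import numpy as np

from pas_atlas.similarity import SimilarityGraph, _matrix_with_x


def sw_score_oracle(a: str, b: str, matrix: str = "BLOSUM62",
                    gap_open: float = 11, gap_extend: float = 1) -> float:
    """Brute-force recursive Smith-Waterman score with affine gaps
    (a gap of length L costs gap_open + L * gap_extend)."""
    mat = _matrix_with_x(matrix)
    neg = float("-inf")
    oc = gap_open + gap_extend

    @lru_cache(maxsize=None)
    def match(i, j):
        if i == 0 or j == 0:
            return neg
        s = mat[a[i - 1], b[j - 1]]
        return s + max(0.0, match(i - 1, j - 1), gap_a(i - 1, j - 1), gap_b(i - 1, j - 1))

    @lru_cache(maxsize=None)
    def gap_a(i, j):  # gap in b, consuming a
        if i == 0:
            return neg
        return max(match(i - 1, j) - oc, gap_a(i - 1, j) - gap_extend)

    @lru_cache(maxsize=None)
    def gap_b(i, j):  # gap in a, consuming b
        if j == 0:
            return neg
        return max(match(i, j - 1) - oc, gap_b(i, j - 1) - gap_extend)

    best = 0.0
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            best = max(best, match(i, j))
    return best


def union_find_components(graph: SimilarityGraph) -> list[frozenset[str]]:
    """Connected components by union-find."""
    nodes = sorted(graph.nodes)
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (u, v) in graph.edges:
        parent[find(u)] = find(v)
    comps: dict[str, set[str]] = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return [frozenset(c) for c in comps.values()]


def random_clique_graph(rng: np.random.Generator, max_nodes: int = 40,
                        weight: float = 1.0) -> SimilarityGraph:
    """A graph whose connected components are cliques of random sizes 1-8."""
    g = SimilarityGraph()
    label = 0
    total = 0
    while total < max_nodes - 1:
        k = int(rng.integers(1, min(9, max_nodes - total) + 1))
        nodes = [f"n{label + i:03d}" for i in range(k)]
        label += k
        total += k
        for i in range(k):
            g.add_node(nodes[i])
            for j in range(i + 1, k):
                g.add_edge(nodes[i], nodes[j], weight)
    return g
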