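"""Independent oracles used by the test suite.

Deliberately naive implementations (exact rational arithmetic, exhaustive
enumeration, alternative algorithms) kept separate from the package code
they validate.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import floyd_warshall
from scipy.sparse import csr_matrix


def exact_hypergeom_tail(k: int, universe: int, group: int, module: int) -> float:
    """P(X >= k) by exact rational summation of hypergeometric terms."""
    lo, hi = max(0, module + group - universe), min(module, group)
    if k > hi:
        return 0.0
    denom = comb(universe, module)
    acc = Fraction(0)
    for i in range(max(k, lo), hi + 1):
        acc += Fraction(comb(group, i) * comb(universe - group, module - i), denom)
    return float(acc)


def bfs_distances(graph: nx.Graph, source) -> dict:
    """Breadth-first-search shortest path lengths (networkx BFS)."""
    return dict(nx.single_source_shortest_path_length(graph, source))


def floyd_warshall_matrix(graph: nx.Graph):
    """All-pairs distances via scipy Floyd-Warshall; returns (nodes, matrix)."""
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols = [], []
    for u, v in graph.edges:
        rows += [idx[u], idx[v]]
        cols += [idx[v], idx[u]]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return nodes, floyd_warshall(adj, directed=False, unweighted=True)


def brute_group_summary(dist_row: dict, members) -> tuple:
    """(min, max, mean, n_reachable, n_total) over reachable group members."""
    vals = [dist_row[m] for m in members if m in dist_row]
    if not vals:
        return (None, None, None, 0, len(list(members)))
    return (min(vals), max(vals), sum(vals) / len(vals), len(vals), len(set(members)))
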