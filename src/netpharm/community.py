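"""Topological module detection on the interaction network.

Partitions the PPI graph into disjoint communities by modularity
maximization (Clauset-Newman-Moore greedy agglomeration, the default) or
asynchronous label propagation, then labels them M1..Mk in decreasing-size
order. Communities smaller than ``min_size`` are folded into a reserved
``M0-unassigned`` label that downstream enrichment skips: one- and
two-gene modules cannot support a meaningful overlap test.

Determinism: the input graph is canonicalized (sorted nodes and edges)
before detection, so the result depends only on the network's node/edge
sets, the method, and the seed — never on input file ordering.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import networkx as nx

from .types import UNASSIGNED_LABEL, ConsistencyError, InputError, ModulePartition

METHODS = ("greedy-modularity", "label-propagation")


def _canonical(graph: nx.Graph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(sorted(graph.nodes))
    g.add_edges_from(sorted(tuple(sorted(e)) for e in graph.edges))
    return g


def modularity(graph: nx.Graph, assignment: Mapping[str, str]) -> float:
    """Newman modularity Q = sum_c (e_c/m - (d_c/2m)^2) of a node labelling.

    ``assignment`` maps every node to a community label (any hashable;
    module labels and planted ground-truth labels both work).
    """
    missing = set(graph.nodes) - set(assignment)
    if missing:
        raise ConsistencyError(f"nodes missing from partition: {sorted(missing)[:5]}")
    if graph.number_of_edges() == 0:
        raise InputError("modularity undefined for a network with no edges")
    groups: dict[str, set[str]] = {}
    for node in graph.nodes:
        groups.setdefault(assignment[node], set()).add(node)
    return float(nx.community.modularity(graph, groups.values()))


def detect_modules(
    graph: nx.Graph,
    method: str = "greedy-modularity",
    seed: int = 0,
    min_size: int = 3,
) -> ModulePartition:
    """Detect topological modules and label them M1..Mk.

    Parameters
    ----------
    method
        ``greedy-modularity`` (deterministic; ``seed`` ignored) or
        ``label-propagation`` (stochastic; seeded).
    min_size
        Communities with fewer nodes are folded into ``M0-unassigned``.

    The stored ``modularity_score`` is Q of the raw detected community
    structure, before the min-size fold.
    """
    if graph.number_of_nodes() == 0:
        raise InputError("cannot detect modules on an empty network")
    if graph.number_of_edges() == 0:
        raise InputError("cannot detect modules on a network with no edges")
    if min_size < 1:
        raise InputError(f"min_size must be >= 1, got {min_size}")
    if method not in METHODS:
        raise InputError(f"unknown detection method {method!r}; choose from {METHODS}")

    g = _canonical(graph)
    if method == "greedy-modularity":
        communities = [set(c) for c in nx.community.greedy_modularity_communities(g)]
    else:
        communities = [set(c) for c in nx.community.asyn_lpa_communities(g, seed=seed)]

    raw_assignment = {node: i for i, comm in enumerate(communities) for node in comm}
    score = modularity(g, raw_assignment)

    # order real modules by decreasing size, ties by smallest member gene
    kept = [c for c in communities if len(c) >= min_size]
    kept.sort(key=lambda c: (-len(c), min(c)))
    assignment: dict[str, str] = {}
    for i, comm in enumerate(kept, start=1):
        for node in comm:
            assignment[node] = f"M{i}"
    for comm in communities:
        if len(comm) < min_size:
            for node in comm:
                assignment[node] = UNASSIGNED_LABEL

    partition = ModulePartition(
        assignment=assignment,
        labels=[f"M{i}" for i in range(1, len(kept) + 1)],
        modularity_score=score,
    )
    partition.validate(graph.nodes)
    return partition


def partition_table(partition: ModulePartition) -> list[tuple[str, str]]:
    """(gene, module_label) rows, sorted for stable output."""
    return sorted(partition.assignment.items())


def partition_summary(partition: ModulePartition) -> list[tuple[str, int]]:
    """(module_label, size) rows in label order, M0-unassigned last."""
    sizes = partition.module_sets()
    rows = [(lab, len(sizes[lab])) for lab in partition.labels]
    n0 = sum(1 for lab in partition.assignment.values() if lab == UNASSIGNED_LABEL)
    if n0:
        rows.append((UNASSIGNED_LABEL, n0))
    return rows


def label_sort_key(label: str):
    """Numeric ordering for labels M1, M2, ... (M0-unassigned sorts first)."""
    try:
        return (0, int(label.lstrip("M").split("-")[0]))
    except ValueError:
        return (1, label)


def relabel_from_ground_truth(labels: Mapping[str, int] | Iterable[tuple[str, int]]):
    """Utility: planted integer labels -> module-style assignment dict."""
    items = labels.items() if isinstance(labels, Mapping) else labels
    return {node: f"M{int(c) + 1}" for node, c in items}
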