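"""Shortest-path proximity of drug targets to gene groups.

Distances are exact unweighted shortest paths (Dijkstra with unit edge
weights; validated elsewhere against breadth-first search, with which it
coincides on unit weights). Each (source target, gene group) pair is
summarized by the min / max / mean distance over the group's *reachable*
members; unreachable members are excluded from the statistics and counted
via ``n_total - n_reachable``. A source belonging to the group contributes
its self-distance 0. Sources with mean distance strictly below the
threshold (default 3) are called strongly-connecting "key" targets.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable

import networkx as nx

from .types import (
    DistanceProfile,
    InputError,
    KeyTargetCall,
    PathSummary,
    SeedGeneSet,
)

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 3.0


def single_source_distances(graph: nx.Graph, source: str) -> DistanceProfile:
    """Dijkstra single-source shortest-path lengths with unit edge weights.

    Nodes in other connected components are absent from the profile
    (unreachable marker). Raises :class:`InputError` if the source is not
    a network node.
    """
    if source not in graph:
        raise InputError(f"source {source!r} is not in the network")
    dist = nx.single_source_dijkstra_path_length(graph, source, weight=lambda u, v, d: 1)
    return DistanceProfile(source=source, distances={n: int(d) for n, d in dist.items()})


def summarize_to_group(profile: DistanceProfile, group: SeedGeneSet) -> PathSummary:
    """Min/max/mean distance from the profile's source to a gene group.

    Unreachable members are excluded from all three statistics; if no
    member is reachable the summary is undefined (NaN statistics) and is
    logged — such pairs never become key-target calls.
    """
    if not group.genes:
        raise InputError(f"group {group.name!r} is empty")
    reachable = [profile.distances[g] for g in group.genes if g in profile.distances]
    n_total = len(group.genes)
    if not reachable:
        log.warning(
            "no member of %r reachable from %s; summary undefined",
            group.name,
            profile.source,
        )
        return PathSummary(
            source=profile.source,
            group_name=group.name,
            min_sp=math.nan,
            max_sp=math.nan,
            avg_sp=math.nan,
            n_reachable=0,
            n_total=n_total,
        )
    return PathSummary(
        source=profile.source,
        group_name=group.name,
        min_sp=float(min(reachable)),
        max_sp=float(max(reachable)),
        avg_sp=sum(reachable) / len(reachable),
        n_reachable=len(reachable),
        n_total=n_total,
    )


def call_key_targets(
    graph: nx.Graph,
    targets: Iterable[str],
    groups: Iterable[SeedGeneSet],
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[list[PathSummary], list[KeyTargetCall], list[str]]:
    """Summarize every (target, group) pair and call key targets.

    A target is key for a group when its mean shortest path to the group's
    reachable members is strictly below ``threshold`` (default 3) and at
    least one member is reachable. Targets absent from the network are
    dropped and returned for logging.

    Groups may be seed gene sets, their aggregates, or module gene sets;
    group genes are intersected with the network nodes.
    """
    if threshold <= 0:
        raise InputError(f"threshold must be positive, got {threshold}")
    groups = list(groups)
    nodes = set(graph.nodes)
    targets = sorted(set(targets))
    dropped = [t for t in targets if t not in nodes]
    kept = [t for t in targets if t in nodes]
    if dropped:
        log.warning("dropped %d target(s) absent from the network: %s", len(dropped), dropped)
    if not kept:
        raise InputError("no drug target is present in the network")

    filtered_groups = []
    for g in groups:
        inside = g.genes & nodes
        if not inside:
            log.warning("group %r has no genes in the network; skipped", g.name)
            continue
        filtered_groups.append(SeedGeneSet(name=g.name, category=g.category, genes=frozenset(inside)))

    summaries: list[PathSummary] = []
    calls: list[KeyTargetCall] = []
    for target in kept:
        profile = single_source_distances(graph, target)
        for group in filtered_groups:
            summary = summarize_to_group(profile, group)
            summaries.append(summary)
            calls.append(
                KeyTargetCall(
                    source=target,
                    group_name=group.name,
                    group_category=group.category,
                    avg_sp=summary.avg_sp,
                    is_key=summary.defined and summary.avg_sp < threshold,
                    threshold=threshold,
                )
            )
    return summaries, calls, dropped
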