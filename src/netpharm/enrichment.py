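"""Fisher exact module-enrichment and generic over-representation analysis.

Every (module, seed gene group) pair is scored with a one-sided Fisher
exact test on the 2x2 overlap table against the network universe, plus a
fold-enrichment "proportion": the ratio of the in-module seed-gene density
to its expectation under uniform placement,

    proportion = (k / module_size) / (group_size / universe_size).

A pair is "positive" when p < alpha (default 0.05, uncorrected; the
Benjamini-Hochberg FDR step is available via ``correction="bh"``).
The one-sided (greater) alternative is used throughout: the question is
over-representation, never depletion.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import replace

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import (
    UNASSIGNED_LABEL,
    AnnotationCollection,
    ConsistencyError,
    EnrichmentRecord,
    InputError,
    ModulePartition,
    PositivityCount,
    SeedGeneSet,
)
from .community import label_sort_key


def hypergeom_tail(k, universe_size, group_size, module_size):
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the group genes falling in a module of ``module_size`` drawn
    from ``universe_size`` genes of which ``group_size`` belong to the
    group. This is the one-sided Fisher exact p-value for enrichment.
    Accepts scalars or numpy arrays for ``k``.
    """
    return stats.hypergeom.sf(np.asarray(k) - 1, universe_size, group_size, module_size)


def fold_enrichment(k: int, module_size: int, group_size: int, universe_size: int) -> float:
    """Observed / expected overlap density; 0 by convention when k = 0."""
    if k == 0:
        return 0.0
    return (k / module_size) / (group_size / universe_size)


def fisher_enrichment(
    module_genes: frozenset[str] | set[str],
    group: SeedGeneSet,
    universe: frozenset[str] | set[str],
    alpha: float = 0.05,
    module_label: str = "",
) -> EnrichmentRecord:
    """One-sided Fisher exact enrichment of a seed group in one module."""
    if not module_genes:
        raise InputError("module gene set is empty")
    if not group.genes:
        raise InputError(f"seed group {group.name!r} is empty")
    if not universe:
        raise InputError("universe is empty")
    if not 0 < alpha < 1:
        raise InputError(f"alpha must be in (0, 1), got {alpha}")
    if not set(module_genes) <= set(universe):
        raise ConsistencyError("module genes not contained in the universe")
    if not set(group.genes) <= set(universe):
        raise ConsistencyError(f"group {group.name!r} not contained in the universe")

    n_univ = len(universe)
    n_mod = len(module_genes)
    n_grp = len(group.genes)
    k = len(set(module_genes) & group.genes)
    p = float(hypergeom_tail(k, n_univ, n_grp, n_mod))
    p = min(max(p, 0.0), 1.0)
    return EnrichmentRecord(
        module_label=module_label,
        group_name=group.name,
        group_category=group.category,
        k=k,
        module_size=n_mod,
        group_size=n_grp,
        universe_size=n_univ,
        p_value=p,
        proportion=fold_enrichment(k, n_mod, n_grp, n_univ),
        positive=p < alpha,
    )


def _apply_bh(records: list[EnrichmentRecord], alpha: float) -> list[EnrichmentRecord]:
    """Recompute positivity from Benjamini-Hochberg rejections (p kept raw)."""
    if not records:
        return records
    reject, *_ = multipletests([r.p_value for r in records], alpha=alpha, method="fdr_bh")
    return [replace(rec, positive=bool(rej)) for rec, rej in zip(records, reject)]


def enrich_all(
    partition: ModulePartition,
    groups: Iterable[SeedGeneSet],
    universe: frozenset[str] | set[str],
    alpha: float = 0.05,
    correction: str | None = None,
) -> tuple[list[EnrichmentRecord], list[PositivityCount]]:
    """Score every (module, group) pair; modules labelled M0-unassigned are skipped.

    Returns records ordered by (module label, ascending p-value) and the
    per-module positivity counts. ``correction="bh"`` replaces the raw
    p < alpha positivity rule with Benjamini-Hochberg rejections across
    all tested pairs.
    """
    groups = list(groups)
    module_sets = partition.module_sets()
    testable = [lab for lab in partition.labels if lab != UNASSIGNED_LABEL]
    if not testable or not groups:
        raise InputError("no testable (module, group) pairs")

    records: list[EnrichmentRecord] = []
    for label in sorted(testable, key=label_sort_key):
        for group in groups:
            records.append(
                fisher_enrichment(
                    module_sets[label], group, universe, alpha=alpha, module_label=label
                )
            )
    if correction == "bh":
        records = _apply_bh(records, alpha)
    elif correction not in (None, "none"):
        raise InputError(f"unknown correction {correction!r}")

    records.sort(key=lambda r: (label_sort_key(r.module_label), r.p_value, r.group_name))
    counts = positivity_counts(records)
    return records, counts


def positivity_counts(records: Iterable[EnrichmentRecord]) -> list[PositivityCount]:
    """Number of positive (p < alpha) results per module, in label order."""
    tally: dict[str, int] = {}
    for rec in records:
        tally.setdefault(rec.module_label, 0)
        if rec.positive:
            tally[rec.module_label] += 1
    return [
        PositivityCount(module_label=lab, n_positive=tally[lab])
        for lab in sorted(tally, key=label_sort_key)
    ]


def ora(
    query: frozenset[str] | set[str],
    annotations: AnnotationCollection,
    universe: frozenset[str] | set[str],
    alpha: float = 0.05,
) -> tuple[list[EnrichmentRecord], list[str]]:
    """Over-representation of a query gene list against annotation sets.

    Each annotation set is intersected with the universe before testing;
    sets with zero universe overlap are skipped and reported. Results are
    EnrichmentRecord-shaped with the set name in ``group_name`` and the
    query as the "module" side, ordered by ascending p-value.
    """
    query = set(query)
    if not query:
        raise InputError("empty query gene set")
    if not query <= set(universe):
        raise ConsistencyError("query genes not contained in the universe")
    records: list[EnrichmentRecord] = []
    skipped: list[str] = []
    for name in sorted(annotations.sets):
        members = annotations.sets[name] & set(universe)
        if not members:
            skipped.append(name)
            continue
        group = SeedGeneSet(name=name, category="annotation", genes=frozenset(members))
        records.append(
            fisher_enrichment(query, group, universe, alpha=alpha, module_label="query")
        )
    records.sort(key=lambda r: (r.p_value, r.group_name))
    return records, skipped
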