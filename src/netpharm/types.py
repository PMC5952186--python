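"""Domain types shared across the pipeline.

The pipeline's in-memory graph container is :class:`networkx.Graph` with
uppercase gene symbols as node keys; the dataclasses here carry everything
else that flows between stages (seed gene sets, module partitions,
enrichment records, path summaries, key-target calls).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

SEED_CATEGORIES = ("disease", "symptom", "herb")
AGGREGATE_CATEGORIES = ("aggregate-diseases", "aggregate-symptoms", "aggregate-herbs")

#: canonical names of the aggregate (union) seed groups, mirroring the
#: "Diseases" / "Symptoms" / "Herbs" rows of the published summary tables
AGGREGATE_NAMES = {
    "disease": "Diseases",
    "symptom": "Symptoms",
    "herb": "Herbs",
}

UNASSIGNED_LABEL = "M0-unassigned"


class InputError(ValueError):
    """A required input is missing, unreadable, or semantically empty."""


class ParseError(ValueError):
    """A line or column of an input file could not be interpreted."""


class ConsistencyError(RuntimeError):
    """An internal invariant was violated (indicates a pipeline bug)."""


def normalize_gene(symbol: str) -> str:
    """Normalize a gene symbol: strip surrounding whitespace, uppercase.

    Idempotent by construction. No alias or ortholog mapping is attempted;
    symbols are taken at face value, as in manually curated datasets.
    Raises :class:`ParseError` for empty symbols or internal whitespace.
    """
    s = symbol.strip().upper()
    if not s:
        raise ParseError("empty gene symbol")
    if any(c.isspace() for c in s):
        raise ParseError(f"gene symbol contains internal whitespace: {symbol!r}")
    return s


@dataclass(frozen=True)
class SeedGeneSet:
    """A named gene group used as the query side of enrichment / path tests.

    Categories: ``disease`` / ``symptom`` / ``herb`` for individual groups,
    ``aggregate-*`` for the union groups, plus free-form categories
    (``module``, ``annotation``) for internally constructed groups.
    """

    name: str
    category: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise InputError("seed gene set requires a non-empty name")
        if not self.genes:
            raise InputError(f"seed gene set {self.name!r} is empty")


@dataclass(frozen=True)
class HerbTargetRecord:
    """One herb -> ingredient -> protein-target association with provenance."""

    herb: str
    ingredient: str
    target: str
    source: str = ""

    def __post_init__(self) -> None:
        if not (self.herb and self.ingredient and self.target):
            raise ParseError("herb, ingredient and target must all be non-empty")


@dataclass
class ModulePartition:
    """Disjoint cover of network nodes into labelled topological modules.

    ``assignment`` maps every node to a label; ``labels`` lists the real
    module labels M1..Mk in decreasing-size order. Nodes folded away for
    being in undersized communities carry the reserved ``M0-unassigned``
    label, which is not listed in ``labels`` and is skipped downstream.
    """

    assignment: dict[str, str]
    labels: list[str]
    modularity_score: float

    def members(self, label: str) -> frozenset[str]:
        return frozenset(g for g, lab in self.assignment.items() if lab == label)

    def module_sets(self) -> dict[str, frozenset[str]]:
        """Label -> member set for the real (non-reserved) modules."""
        out: dict[str, set[str]] = {lab: set() for lab in self.labels}
        for g, lab in self.assignment.items():
            if lab in out:
                out[lab].add(g)
        return {lab: frozenset(s) for lab, s in out.items()}

    def validate(self, nodes) -> None:
        """Check the disjoint-cover invariants against a node collection."""
        nodes = set(nodes)
        if set(self.assignment) != nodes:
            raise ConsistencyError("partition does not cover the node set exactly")
        expect = [f"M{i}" for i in range(1, len(self.labels) + 1)]
        if self.labels != expect:
            raise ConsistencyError(f"labels not contiguous M1..Mk: {self.labels}")
        if not (-0.5 - 1e-12 <= self.modularity_score <= 1 + 1e-12):
            raise ConsistencyError(f"modularity out of range: {self.modularity_score}")


@dataclass(frozen=True)
class EnrichmentRecord:
    """One module x seed-group Fisher enrichment result.

    ``proportion`` is the fold enrichment
    (k / module_size) / (group_size / universe_size), reported as 0 when
    the overlap k is 0. ``positive`` applies the strict p < alpha rule.
    """

    module_label: str
    group_name: str
    group_category: str
    k: int
    module_size: int
    group_size: int
    universe_size: int
    p_value: float
    proportion: float
    positive: bool

    def __post_init__(self) -> None:
        if not 0 <= self.k <= min(self.module_size, self.group_size):
            raise ConsistencyError(
                f"overlap {self.k} inconsistent with sizes "
                f"({self.module_size}, {self.group_size})"
            )
        if not 0.0 <= self.p_value <= 1.0:
            raise ConsistencyError(f"p-value out of [0,1]: {self.p_value}")


@dataclass(frozen=True)
class PositivityCount:
    module_label: str
    n_positive: int


@dataclass
class DistanceProfile:
    """Unweighted shortest-path distances from one source node.

    ``distances`` holds reachable nodes only; absence marks unreachability.
    """

    source: str
    distances: dict[str, int]

    def distance(self, node: str) -> int | None:
        return self.distances.get(node)


@dataclass(frozen=True)
class PathSummary:
    """Min/max/mean shortest path from a source to a gene group.

    Statistics are over reachable members only; ``n_reachable`` /
    ``n_total`` make the exclusion explicit. When no member is reachable
    the summary is undefined (``defined=False``, statistics NaN) and is
    excluded from key-target calling.
    """

    source: str
    group_name: str
    min_sp: float
    max_sp: float
    avg_sp: float
    n_reachable: int
    n_total: int

    @property
    def defined(self) -> bool:
        return self.n_reachable > 0

    def __post_init__(self) -> None:
        if self.n_reachable > self.n_total:
            raise ConsistencyError("n_reachable exceeds n_total")
        if self.defined and not (self.min_sp <= self.avg_sp <= self.max_sp):
            raise ConsistencyError("min_sp <= avg_sp <= max_sp violated")


@dataclass(frozen=True)
class KeyTargetCall:
    """Strongly-connecting call for one (source, group): avg_sp < threshold."""

    source: str
    group_name: str
    group_category: str
    avg_sp: float
    is_key: bool
    threshold: float = 3.0

    def __post_init__(self) -> None:
        reachable = not math.isnan(self.avg_sp)
        expect = reachable and self.avg_sp < self.threshold
        if self.is_key != expect:
            raise ConsistencyError("is_key inconsistent with avg_sp/threshold")


@dataclass
class CandidateTarget:
    """A drug target key for >=1 selected module AND both phenotype unions."""

    gene: str
    supporting: list[tuple[str, float]]
    modules_hit: list[str]

    @property
    def mean_avg_sp(self) -> float:
        return sum(a for _, a in self.supporting) / len(self.supporting)


@dataclass
class KeyModuleSelection:
    """Modules selected as disease-relevant from enrichment positivity counts."""

    selected: list[str]
    rule: str
    counts: list[PositivityCount] = field(default_factory=list)


@dataclass
class AnnotationCollection:
    """Named gene sets (pathways / ontology terms) for over-representation."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise InputError(f"annotation set {name!r} is empty")
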