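"""Synthetic input generator with planted structure.

Real PPI networks, curated phenotype-gene tables and herb-target tables
are version-dependent and not redistributable, so the pipeline is
exercised on synthetic inputs that carry the statistical structure the
analysis assumes, with known ground truth:

* a planted-partition (stochastic block model) network — controllable
  community contrast via within/between edge probabilities ``p_in`` /
  ``p_out``;
* seed gene groups with a controlled expected fold enrichment in a chosen
  planted module;
* a proximal "drug target" node wired to a chosen fraction of the planted
  module (the strongly-connecting key-target pattern), plus weakly wired
  decoy targets and a degree-matched randomly wired control.

This is a deliberate simplification of real interactome topology: block
models have Poisson-like degrees, not the heavy-tailed degree
distributions of curated PPI networks.

All generators are seeded and byte-reproducible. Synthetic genes are named
``G000001``..; the planted proximal target is ``TGT1``, decoys ``DEC*``,
the degree-matched control ``CTL1``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from .io import write_gmt, write_network
from .types import AnnotationCollection, InputError, SeedGeneSet

PLANTED_TARGET = "TGT1"
CONTROL_TARGET = "CTL1"


@dataclass
class SyntheticSpec:
    """Parameters of one planted-structure instance.

    Defaults define the standard benchmark: 120 genes in 4 equal
    communities with strong contrast (p_in = 0.3, p_out = 0.01), a
    15-gene seed group at fold 4 in a 30-gene planted module, and a target
    wired to half the planted module.
    """

    n_nodes: int = 120
    n_communities: int = 4
    p_in: float = 0.3
    p_out: float = 0.01
    planted_module: int = 0
    group_size: int = 15
    fold: float = 4.0
    attach_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1 or self.n_communities < 1:
            raise InputError("n_nodes and n_communities must be positive")
        if self.n_communities > self.n_nodes:
            raise InputError("more communities than nodes")
        if not (0 <= self.p_out < self.p_in <= 1):
            raise InputError("need 0 <= p_out < p_in <= 1")
        if not 0 < self.attach_fraction <= 1:
            raise InputError("attach_fraction must be in (0, 1]")
        if self.fold < 1:
            raise InputError("fold must be >= 1")
        if not 0 < self.group_size <= self.n_nodes:
            raise InputError("group_size must be in 1..n_nodes")
        if not 0 <= self.planted_module < self.n_communities:
            raise InputError("planted_module out of range")


def _gene(i: int) -> str:
    return f"G{i + 1:06d}"


def _community_sizes(spec: SyntheticSpec) -> list[int]:
    base, extra = divmod(spec.n_nodes, spec.n_communities)
    return [base + (1 if i < extra else 0) for i in range(spec.n_communities)]


def generate_network(spec: SyntheticSpec) -> tuple[nx.Graph, dict[str, int]]:
    """Planted-partition random graph plus ground-truth community labels.

    Nodes are split into near-equal communities; each within-community
    pair is an edge with probability ``p_in``, each between-community pair
    with probability ``p_out`` (independent Bernoulli draws, seeded).
    """
    sizes = _community_sizes(spec)
    probs = [
        [spec.p_in if i == j else spec.p_out for j in range(spec.n_communities)]
        for i in range(spec.n_communities)
    ]
    sbm = nx.stochastic_block_model(sizes, probs, seed=spec.seed)
    labels: dict[str, int] = {}
    block_of = {}
    for c, block in enumerate(sbm.graph["partition"]):
        for i in block:
            block_of[i] = c
    mapping = {i: _gene(i) for i in sbm.nodes}
    graph = nx.relabel_nodes(nx.Graph(sbm.edges), mapping)
    graph.add_nodes_from(mapping.values())
    for i, name in mapping.items():
        labels[name] = block_of[i]
    return graph, labels


def max_feasible_fold(spec: SyntheticSpec) -> float:
    """Largest fold keeping the in-module probability <= 1 and the
    expected in-module overlap <= module size."""
    sizes = _community_sizes(spec)
    m = sizes[spec.planted_module]
    return min(spec.n_nodes / m, spec.n_nodes / spec.group_size)


def generate_seed_group(
    labels: dict[str, int],
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    name: str = "SeedGroup",
    category: str = "disease",
) -> SeedGeneSet:
    """Sample a seed gene group with controlled expected module overlap.

    The expected number of group genes inside the planted module equals
    ``fold * (module_size / n_nodes) * group_size``: the in-module count is
    Binomial(group_size, fold * module_size / n_nodes), then members are
    drawn without replacement inside / outside the module. ``fold = 1``
    reproduces the uniform (hypergeometric-mean) baseline.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    inside = sorted(g for g, c in labels.items() if c == spec.planted_module)
    outside = sorted(g for g, c in labels.items() if c != spec.planted_module)
    if not inside:
        raise InputError("planted module is empty")
    m, n = len(inside), len(labels)
    p_star = spec.fold * m / n
    expected = p_star * spec.group_size
    if p_star > 1 + 1e-12 or expected > m + 1e-9:
        fmax = min(n / m, n / spec.group_size)
        raise InputError(
            f"fold {spec.fold} infeasible for module {m}/{n} and group "
            f"{spec.group_size}; maximum feasible fold is {fmax:g}"
        )
    p_star = min(p_star, 1.0)
    k_in = int(rng.binomial(spec.group_size, p_star))
    k_in = min(k_in, m)
    k_in = max(k_in, spec.group_size - len(outside))
    chosen = list(rng.choice(inside, size=k_in, replace=False))
    chosen += list(rng.choice(outside, size=spec.group_size - k_in, replace=False))
    return SeedGeneSet(name=name, category=category, genes=frozenset(chosen))


def plant_proximal_target(
    graph: nx.Graph,
    labels: dict[str, int],
    spec: SyntheticSpec,
    name: str = PLANTED_TARGET,
) -> str:
    """Add a target node wired to ``attach_fraction`` of the planted module.

    Attaches to ``ceil(attach_fraction * module_size)`` distinct module
    nodes chosen uniformly (seeded); returns the new node's id.
    """
    inside = sorted(g for g, c in labels.items() if c == spec.planted_module)
    if not inside:
        raise InputError("planted module is empty")
    n_attach = math.ceil(spec.attach_fraction * len(inside))
    if n_attach == 0:
        raise InputError("attach count is zero")
    rng = np.random.default_rng(spec.seed + 1)
    anchors = rng.choice(inside, size=n_attach, replace=False)
    graph.add_node(name)
    for a in anchors:
        graph.add_edge(name, str(a))
    return name


def plant_random_target(
    graph: nx.Graph,
    n_attach: int,
    seed: int,
    name: str = CONTROL_TARGET,
    candidates: list[str] | None = None,
) -> str:
    """Add a degree-matched control wired to ``n_attach`` uniform nodes.

    The null counterpart of :func:`plant_proximal_target`: same degree,
    attachment points drawn from the whole node set (or ``candidates``)
    instead of the planted module.
    """
    pool = sorted(candidates if candidates is not None else graph.nodes)
    pool = [p for p in pool if p != name]
    if n_attach < 1 or n_attach > len(pool):
        raise InputError(f"cannot attach to {n_attach} of {len(pool)} nodes")
    rng = np.random.default_rng(seed)
    anchors = rng.choice(pool, size=n_attach, replace=False)
    graph.add_node(name)
    for a in anchors:
        graph.add_edge(name, str(a))
    return name


# ---------------------------------------------------------------------------
# full input bundle


def make_input_bundle(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, str]:
    """Emit a complete, self-consistent input bundle for the pipeline.

    Writes an edge-list TSV, a seed-set TSV (diseases and symptoms
    enriched in the planted module at ``spec.fold``), an
    herb-ingredient-target TSV whose targets are the planted proximal
    target plus two weakly wired decoys, a GMT annotation collection, and
    the spec itself as YAML. Returns the file paths keyed by role.

    The construction mirrors the key-target pattern: seed phenotype genes
    concentrate in the planted module; the planted target ``TGT1`` sits
    one edge away from half of that module, while decoys ``DEC1``/``DEC2``
    hang off single distant communities and should fail the proximity
    conjunction.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    graph, labels = generate_network(spec)
    rng = np.random.default_rng(spec.seed + 2)

    # phenotype seed sets, all enriched in the planted module
    seed_rows: list[tuple[str, str, str]] = []
    for i in range(2):
        s = generate_seed_group(labels, spec, rng, name=f"Disease_{i + 1}", category="disease")
        seed_rows += [(s.name, "disease", g) for g in sorted(s.genes)]
    for i in range(2):
        s = generate_seed_group(labels, spec, rng, name=f"Symptom_{i + 1}", category="symptom")
        seed_rows += [(s.name, "symptom", g) for g in sorted(s.genes)]

    # targets: one proximal, two decoys on non-planted communities
    tgt = plant_proximal_target(graph, labels, spec)
    other = [c for c in range(spec.n_communities) if c != spec.planted_module]
    decoys = []
    for j, comm in enumerate(other[:2]):
        pool = sorted(g for g, c in labels.items() if c == comm)
        name = f"DEC{j + 1}"
        plant_random_target(graph, min(2, len(pool)), spec.seed + 10 + j,
                            name=name, candidates=pool)
        decoys.append(name)

    herb_rows = [("Herb_A", "ingredient_a1", tgt, "synthetic")]
    for j, d in enumerate(decoys):
        herb_rows.append(("Herb_A", f"ingredient_a{j + 2}", d, "synthetic"))
        herb_rows.append(("Herb_B", f"ingredient_b{j + 1}", d, "synthetic"))
    # duplicate record on purpose: exercises the keep-one-record rule
    herb_rows.append(herb_rows[0])

    # annotations: one pathway concentrated in the planted module, two random
    inside = sorted(g for g, c in labels.items() if c == spec.planted_module)
    ann_sets = {
        "PW_PLANTED": frozenset(list(rng.choice(inside, size=min(20, len(inside)),
                                                replace=False)) + [tgt]),
    }
    all_nodes = sorted(labels)
    for i in range(2):
        ann_sets[f"PW_RANDOM_{i + 1}"] = frozenset(
            rng.choice(all_nodes, size=15, replace=False)
        )
    annotations = AnnotationCollection(sets=ann_sets)

    paths = {
        "network": str(out / "edge_list.tsv"),
        "seed_sets": str(out / "seed_sets.tsv"),
        "herb_table": str(out / "herb_table.tsv"),
        "annotations": str(out / "annotations.gmt"),
        "spec": str(out / "spec.yaml"),
        "labels": str(out / "planted_labels.tsv"),
    }
    write_network(graph, paths["network"])
    with open(paths["seed_sets"], "w", encoding="utf-8") as fh:
        fh.write("# name\tcategory\tgene\n")
        for name, cat, gene in seed_rows:
            fh.write(f"{name}\t{cat}\t{gene}\n")
    with open(paths["herb_table"], "w", encoding="utf-8") as fh:
        fh.write("herb\tingredient\ttarget\tsource\n")
        for row in herb_rows:
            fh.write("\t".join(row) + "\n")
    write_gmt(annotations, paths["annotations"])
    with open(paths["spec"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(spec), fh, sort_keys=True)
    with open(paths["labels"], "w", encoding="utf-8") as fh:
        fh.write("# gene\tplanted_community\n")
        for g in sorted(labels):
            fh.write(f"{g}\t{labels[g]}\n")
    return paths
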