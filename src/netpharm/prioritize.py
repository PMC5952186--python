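"""Key-module selection, candidate-target intersection, and the pipeline driver.

The prioritization logic mirrors the network-pharmacology recipe: modules
are ranked by how many seed gene groups enrich in them (positivity count),
the top modules are selected, and a drug target becomes a *candidate* when
it is a strongly-connecting key target simultaneously for at least one
selected module, for the union of all co-morbid disease genes, and for the
union of all co-morbid symptom genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .community import detect_modules, label_sort_key, partition_summary, partition_table
from .enrichment import enrich_all, ora
from .io import (
    LoadReport,
    herb_seed_sets,
    read_gmt,
    read_herb_table,
    read_network,
    read_seed_sets,
)
from .paths import DEFAULT_THRESHOLD, call_key_targets
from .types import (
    AnnotationCollection,
    CandidateTarget,
    EnrichmentRecord,
    InputError,
    KeyModuleSelection,
    KeyTargetCall,
    ModulePartition,
    PathSummary,
    PositivityCount,
    SeedGeneSet,
)

log = logging.getLogger(__name__)

SELECTION_RULES = ("top_n", "min_positive")


def select_key_modules(
    counts: list[PositivityCount],
    rule: str = "top_n",
    param: int = 2,
) -> KeyModuleSelection:
    """Select disease-relevant modules from enrichment positivity counts.

    ``top_n``: the ``param`` modules with the highest positivity counts
    (modules with zero positives never qualify). ``min_positive``: every
    module with at least ``param`` positive results. Ordering is by
    descending count, ties broken by module label. An empty selection is
    a warning, not an error.
    """
    if not counts:
        raise InputError("no positivity counts to select from")
    if param < 1:
        raise InputError(f"selection param must be >= 1, got {param}")
    if rule not in SELECTION_RULES:
        raise InputError(f"unknown selection rule {rule!r}; choose from {SELECTION_RULES}")
    ranked = sorted(counts, key=lambda c: (-c.n_positive, label_sort_key(c.module_label)))
    if rule == "top_n":
        chosen = [c for c in ranked if c.n_positive > 0][:param]
    else:
        chosen = [c for c in ranked if c.n_positive >= param]
    if not chosen:
        log.warning("no module qualifies under rule %s(%d); empty selection", rule, param)
    return KeyModuleSelection(
        selected=[c.module_label for c in chosen],
        rule=f"{rule}({param})",
        counts=ranked,
    )


def intersect_key_targets(
    calls: list[KeyTargetCall],
    selection: KeyModuleSelection,
) -> list[CandidateTarget]:
    """Candidate targets: key for >=1 selected module AND both phenotype unions.

    ``calls`` must include calls against the aggregate-diseases and
    aggregate-symptoms groups. Output is sorted by mean avg_sp ascending
    (lower proximity ranks first).
    """
    cats = {c.group_category for c in calls}
    for needed in ("aggregate-diseases", "aggregate-symptoms"):
        if needed not in cats:
            raise InputError(f"key-target calls are missing the {needed} group")

    by_source: dict[str, list[KeyTargetCall]] = {}
    for c in calls:
        by_source.setdefault(c.source, []).append(c)

    selected = set(selection.selected)
    candidates: list[CandidateTarget] = []
    for source in sorted(by_source):
        mine = by_source[source]
        module_hits = [
            c for c in mine
            if c.group_category == "module" and c.group_name in selected and c.is_key
        ]
        disease = [c for c in mine if c.group_category == "aggregate-diseases" and c.is_key]
        symptom = [c for c in mine if c.group_category == "aggregate-symptoms" and c.is_key]
        if module_hits and disease and symptom:
            supporting = [
                (c.group_name, c.avg_sp) for c in module_hits + disease + symptom
            ]
            candidates.append(
                CandidateTarget(
                    gene=source,
                    supporting=supporting,
                    modules_hit=sorted((c.group_name for c in module_hits), key=label_sort_key),
                )
            )
    candidates.sort(key=lambda c: (c.mean_avg_sp, c.gene))
    return candidates


def pathway_key_overlap(
    annotations: AnnotationCollection,
    module_genes: frozenset[str] | set[str],
    key_targets: frozenset[str] | set[str],
) -> list[tuple[str, int, int]]:
    """Per annotation set: (|set ∩ module|, |set ∩ module ∩ key targets|).

    Functional-pathway summary of a module: how many module genes each
    pathway covers and how many of those are key drug targets. Empty
    intersections yield zeros.
    """
    if not annotations.sets or not module_genes:
        raise InputError("annotation collection and module genes must be non-empty")
    module_genes = set(module_genes)
    key_targets = set(key_targets)
    rows = []
    for name in sorted(annotations.sets):
        in_module = annotations.sets[name] & module_genes
        rows.append((name, len(in_module), len(in_module & key_targets)))
    return rows


# ---------------------------------------------------------------------------
# pipeline driver


@dataclass
class PipelineConfig:
    """Everything a full run needs: input paths and analysis parameters."""

    network: str
    seed_sets: str
    herb_table: str
    annotations: str | None = None
    network_format: str = "tsv"
    alpha: float = 0.05
    threshold: float = DEFAULT_THRESHOLD
    method: str = "greedy-modularity"
    seed: int = 0
    min_size: int = 3
    selection_rule: str = "top_n"
    selection_param: int = 2
    correction: str | None = None
    skip_bad_lines: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class ReportBundle:
    """In-memory results of a full pipeline run."""

    config: PipelineConfig
    graph: nx.Graph
    partition: ModulePartition
    seed_groups: list[SeedGeneSet]
    herb_groups: list[SeedGeneSet]
    enrichment: list[EnrichmentRecord]
    positivity: list[PositivityCount]
    selection: KeyModuleSelection
    path_summaries: list[PathSummary]
    key_calls: list[KeyTargetCall]
    candidates: list[CandidateTarget]
    ora_results: dict[str, list[EnrichmentRecord]] = field(default_factory=dict)
    pathway_overlap: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    load_reports: dict[str, LoadReport] = field(default_factory=dict)
    dropped_targets: list[str] = field(default_factory=list)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> ReportBundle:
    """Execute read -> detect -> enrich -> paths -> prioritize.

    If ``out_dir`` is given, all report TSVs plus a run manifest are
    written there; re-running with the same config and seed reproduces
    byte-identical files. Stage failures propagate with the stage name.
    """

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    graph, net_report = stage("read-network", read_network,
                              config.network, config.network_format,
                              skip_bad_lines=config.skip_bad_lines)
    universe = frozenset(graph.nodes)

    seed_groups, seed_report = stage("read-seed-sets", read_seed_sets,
                                     config.seed_sets, graph)
    herb_records, herb_report = stage("read-herb-table", read_herb_table,
                                      config.herb_table)
    herb_groups = herb_seed_sets(herb_records, graph, report=herb_report)
    herb_union = frozenset().union(*(g.genes for g in herb_groups)) if herb_groups else frozenset()
    if not herb_union:
        raise InputError("[read-herb-table] no herb target is present in the network")

    all_groups = list(seed_groups) + list(herb_groups)
    if herb_groups:
        all_groups.append(
            SeedGeneSet(name="Herbs", category="aggregate-herbs", genes=herb_union)
        )
    # drop duplicate aggregate names (seed TSVs normally carry no herb rows)
    seen: set[str] = set()
    groups: list[SeedGeneSet] = []
    for g in all_groups:
        if g.name in seen:
            log.warning("duplicate group name %r; keeping the first", g.name)
            continue
        seen.add(g.name)
        groups.append(g)

    partition = stage("detect-modules", detect_modules, graph,
                      method=config.method, seed=config.seed, min_size=config.min_size)

    enrichment, positivity = stage("enrichment", enrich_all, partition, groups,
                                   universe, alpha=config.alpha,
                                   correction=config.correction)

    selection = stage("select-modules", select_key_modules, positivity,
                      rule=config.selection_rule, param=config.selection_param)

    module_sets = partition.module_sets()
    path_groups = [
        SeedGeneSet(name=lab, category="module", genes=module_sets[lab])
        for lab in selection.selected
    ]
    path_groups += [g for g in groups
                    if g.category in ("aggregate-diseases", "aggregate-symptoms")]
    summaries, calls, dropped_targets = stage(
        "path-analysis", call_key_targets, graph, herb_union, path_groups,
        threshold=config.threshold,
    )

    candidates = stage("prioritize", intersect_key_targets, calls, selection)

    ora_results: dict[str, list[EnrichmentRecord]] = {}
    overlap: dict[str, list[tuple[str, int, int]]] = {}
    if config.annotations:
        annotations = stage("read-annotations", read_gmt, config.annotations)
        key_by_module: dict[str, set[str]] = {}
        for c in calls:
            if c.group_category == "module" and c.is_key:
                key_by_module.setdefault(c.group_name, set()).add(c.source)
        for lab in selection.selected:
            ora_results[lab], _ = stage("ora", ora, module_sets[lab],
                                        annotations, universe, alpha=config.alpha)
            overlap[lab] = stage("pathway-overlap", pathway_key_overlap, annotations,
                                 module_sets[lab], key_by_module.get(lab, set()))

    bundle = ReportBundle(
        config=config,
        graph=graph,
        partition=partition,
        seed_groups=list(seed_groups),
        herb_groups=herb_groups,
        enrichment=enrichment,
        positivity=positivity,
        selection=selection,
        path_summaries=summaries,
        key_calls=calls,
        candidates=candidates,
        ora_results=ora_results,
        pathway_overlap=overlap,
        load_reports={
            "network": net_report,
            "seed_sets": seed_report,
            "herb_table": herb_report,
        },
        dropped_targets=dropped_targets,
    )
    if out_dir is not None:
        write_reports(bundle, out_dir)
    return bundle


# ---------------------------------------------------------------------------
# report writers (stable formatting => byte-identical reruns)


def _fmt_p(p: float) -> str:
    return f"{p:.6g}"


def _fmt_sp(x: float) -> str:
    return "NA" if np.isnan(x) else f"{x:.6f}"


def enrichment_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "module_label": r.module_label,
                "group_name": r.group_name,
                "group_category": r.group_category,
                "k": r.k,
                "module_size": r.module_size,
                "group_size": r.group_size,
                "universe_size": r.universe_size,
                "p_value": _fmt_p(r.p_value),
                "proportion": f"{r.proportion:.6f}",
                "positive": str(r.positive),
            }
            for r in records
        ]
    )


def path_frame(summaries: list[PathSummary], calls: list[KeyTargetCall]) -> pd.DataFrame:
    key = {(c.source, c.group_name): c.is_key for c in calls}
    return pd.DataFrame(
        [
            {
                "source": s.source,
                "group_name": s.group_name,
                "min_sp": _fmt_sp(s.min_sp),
                "max_sp": _fmt_sp(s.max_sp),
                "avg_sp": _fmt_sp(s.avg_sp),
                "n_reachable": s.n_reachable,
                "n_total": s.n_total,
                "is_key": str(key.get((s.source, s.group_name), False)),
            }
            for s in summaries
        ]
    )


def write_reports(bundle: ReportBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def tsv(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, sep="\t", index=False, lineterminator="\n")

    tsv(pd.DataFrame(partition_table(bundle.partition),
                     columns=["gene", "module_label"]), "modules.tsv")
    tsv(pd.DataFrame(partition_summary(bundle.partition),
                     columns=["module_label", "size"]), "module_summary.tsv")
    tsv(enrichment_frame(bundle.enrichment), "enrichment.tsv")
    tsv(pd.DataFrame([{"module_label": c.module_label, "n_positive": c.n_positive}
                      for c in bundle.positivity]), "positivity.tsv")
    tsv(path_frame(bundle.path_summaries, bundle.key_calls), "path_summaries.tsv")
    tsv(pd.DataFrame(
        [
            {
                "gene": c.gene,
                "mean_avg_sp": f"{c.mean_avg_sp:.6f}",
                "modules_hit": ",".join(c.modules_hit),
                "supporting": ";".join(f"{n}={a:.6f}" for n, a in c.supporting),
            }
            for c in bundle.candidates
        ],
        columns=["gene", "mean_avg_sp", "modules_hit", "supporting"],
    ), "candidates.tsv")
    for lab, records in bundle.ora_results.items():
        tsv(enrichment_frame(records), f"ora_{lab}.tsv")
    for lab, rows in bundle.pathway_overlap.items():
        tsv(pd.DataFrame(rows, columns=["set_name", "n_pathway_gene", "n_key_protein"]),
            f"pathway_overlap_{lab}.tsv")

    manifest = {
        "config": bundle.config.to_dict(),
        "versions": {
            "netpharm": __version__,
            "networkx": nx.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "network": {
            "n_nodes": bundle.graph.number_of_nodes(),
            "n_edges": bundle.graph.number_of_edges(),
        },
        "n_modules": len(bundle.partition.labels),
        "modularity": round(bundle.partition.modularity_score, 6),
        "selected_modules": bundle.selection.selected,
        "selection_rule": bundle.selection.rule,
        "n_candidates": len(bundle.candidates),
        "dropped_targets": bundle.dropped_targets,
        "load_reports": {
            name: {
                "n_lines": r.n_lines,
                "n_kept": r.n_kept,
                "n_self_loops": r.n_self_loops,
                "n_duplicates": r.n_duplicates,
                "n_malformed": r.n_malformed,
                "dropped_genes": r.dropped_genes,
                "excluded_sets": r.excluded_sets,
            }
            for name, r in bundle.load_reports.items()
        },
    }
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
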