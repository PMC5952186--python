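"""Readers and writers for the pipeline's external formats.

Edge lists (2-column TSV or SIF), phenotype/herb seed-set TSVs,
herb-ingredient-target TSVs and GMT gene-set collections are all plain
tab-separated text. Parsing is strict by default: a malformed line is fatal
unless ``skip_bad_lines`` is set, in which case it is counted and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .types import (
    AGGREGATE_NAMES,
    SEED_CATEGORIES,
    AnnotationCollection,
    HerbTargetRecord,
    InputError,
    ParseError,
    SeedGeneSet,
    normalize_gene,
)

log = logging.getLogger(__name__)


@dataclass
class LoadReport:
    """Per-file accounting: every input line is kept or counted as dropped."""

    path: str = ""
    n_lines: int = 0
    n_kept: int = 0
    n_self_loops: int = 0
    n_duplicates: int = 0
    n_malformed: int = 0
    dropped_genes: dict[str, list[str]] = field(default_factory=dict)
    excluded_sets: list[str] = field(default_factory=list)

    def check_conservation(self) -> None:
        if self.n_lines != (
            self.n_kept + self.n_self_loops + self.n_duplicates + self.n_malformed
        ):
            raise AssertionError(f"load report does not conserve line counts: {self}")


def _data_lines(path: str | Path):
    """Yield (1-based line number, stripped line), skipping blanks and '#' comments."""
    p = Path(path)
    if not p.is_file():
        raise InputError(f"cannot read input file: {p}")
    with open(p, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield i, line


def read_network(
    path: str | Path,
    fmt: str = "tsv",
    skip_bad_lines: bool = False,
) -> tuple[nx.Graph, LoadReport]:
    """Read an undirected simple interaction network from an edge list.

    Parameters
    ----------
    path
        Edge-list file. ``tsv``: two whitespace/tab-separated gene columns
        per line. ``sif``: ``nodeA <TAB> relation <TAB> nodeB`` (the
        relation column is ignored).
    skip_bad_lines
        Count and log malformed lines instead of raising.

    Returns the graph (normalized uppercase symbols, no self-loops, no
    duplicate edges) and a :class:`LoadReport` accounting for every line.
    Input line order does not affect the result.
    """
    if fmt not in ("tsv", "sif"):
        raise InputError(f"unknown edge-list format: {fmt!r}")
    graph = nx.Graph()
    report = LoadReport(path=str(path))
    for lineno, line in _data_lines(path):
        report.n_lines += 1
        cols = line.split("\t") if "\t" in line else line.split()
        try:
            if fmt == "sif":
                if len(cols) < 3:
                    raise ParseError(
                        f"{path}:{lineno}: SIF line needs 3 columns, got {len(cols)}"
                    )
                a, b = normalize_gene(cols[0]), normalize_gene(cols[2])
            else:
                if len(cols) < 2:
                    raise ParseError(
                        f"{path}:{lineno}: edge line needs >=2 columns, got {len(cols)}"
                    )
                a, b = normalize_gene(cols[0]), normalize_gene(cols[1])
        except ParseError:
            if skip_bad_lines:
                report.n_malformed += 1
                log.warning("skipping malformed line %s:%d: %r", path, lineno, line)
                continue
            raise
        if a == b:
            report.n_self_loops += 1
            continue
        if graph.has_edge(a, b):
            report.n_duplicates += 1
            continue
        graph.add_edge(a, b)
        report.n_kept += 1
    report.check_conservation()
    return graph, report


def write_network(graph: nx.Graph, path: str | Path) -> None:
    """Write an edge list TSV; sorted for byte-identical round trips."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


def read_seed_sets(
    path: str | Path,
    network: nx.Graph,
) -> tuple[list[SeedGeneSet], LoadReport]:
    """Read (name, category, gene) rows into seed gene sets plus aggregates.

    Genes absent from the network are dropped and logged per set; sets that
    become empty are excluded and logged. For each category present, an
    aggregate union set ("Diseases" / "Symptoms" / "Herbs") is appended.
    Raises :class:`InputError` if every set filters to empty.
    """
    report = LoadReport(path=str(path))
    raw: dict[str, tuple[str, set[str]]] = {}
    order: list[str] = []
    for lineno, line in _data_lines(path):
        report.n_lines += 1
        cols = line.split("\t")
        if len(cols) < 3:
            raise ParseError(
                f"{path}:{lineno}: seed-set line needs 3 columns "
                "(name, category, gene)"
            )
        name, category, gene = cols[0].strip(), cols[1].strip().lower(), cols[2]
        if category not in SEED_CATEGORIES:
            raise ParseError(
                f"{path}:{lineno}: unknown category {category!r} "
                f"(expected one of {SEED_CATEGORIES})"
            )
        if name not in raw:
            raw[name] = (category, set())
            order.append(name)
        elif raw[name][0] != category:
            raise ParseError(f"{path}:{lineno}: set {name!r} listed under two categories")
        raw[name][1].add(normalize_gene(gene))
        report.n_kept += 1
    report.check_conservation()

    nodes = set(network.nodes)
    sets: list[SeedGeneSet] = []
    for name in order:
        category, genes = raw[name]
        kept = genes & nodes
        dropped = sorted(genes - nodes)
        if dropped:
            report.dropped_genes[name] = dropped
            log.info("set %r: dropped %d gene(s) absent from network", name, len(dropped))
        if not kept:
            report.excluded_sets.append(name)
            log.warning("set %r excluded: no genes present in the network", name)
            continue
        sets.append(SeedGeneSet(name=name, category=category, genes=frozenset(kept)))
    if not sets:
        raise InputError(f"{path}: all seed sets are empty after network filtering")

    names = [s.name for s in sets]
    if len(names) != len(set(names)):
        raise InputError(f"{path}: duplicate seed set names after filtering")
    return sets + build_aggregates(sets), report


def build_aggregates(sets: list[SeedGeneSet]) -> list[SeedGeneSet]:
    """Union sets per category, named Diseases / Symptoms / Herbs."""
    out = []
    for category in SEED_CATEGORIES:
        member = [s for s in sets if s.category == category]
        if not member:
            continue
        union = frozenset().union(*(s.genes for s in member))
        out.append(
            SeedGeneSet(
                name=AGGREGATE_NAMES[category],
                category=f"aggregate-{category}s",
                genes=union,
            )
        )
    return out


def read_herb_table(path: str | Path) -> tuple[list[HerbTargetRecord], LoadReport]:
    """Read an herb / ingredient / target / source TSV.

    Exact-duplicate (herb, ingredient, target) triples are collapsed to a
    single record (first occurrence wins), matching the curation rule of
    keeping one record per identical association.
    """
    p = Path(path)
    if not p.is_file():
        raise InputError(f"cannot read herb table: {p}")
    df = pd.read_csv(p, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = {"herb", "ingredient", "target"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: missing column(s) {sorted(required - set(df.columns))}"
        )
    if "source" not in df.columns:
        df["source"] = ""
    report = LoadReport(path=str(path), n_lines=len(df))
    records: list[HerbTargetRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for row in df.itertuples(index=False):
        rec = HerbTargetRecord(
            herb=row.herb.strip(),
            ingredient=row.ingredient.strip(),
            target=normalize_gene(row.target),
            source=row.source.strip(),
        )
        key = (rec.herb, rec.ingredient, rec.target)
        if key in seen:
            report.n_duplicates += 1
            continue
        seen.add(key)
        records.append(rec)
        report.n_kept += 1
    report.check_conservation()
    return records, report


def herb_seed_sets(
    records: list[HerbTargetRecord],
    network: nx.Graph,
    report: LoadReport | None = None,
) -> list[SeedGeneSet]:
    """Per-herb target sets (network-filtered) in herb first-appearance order."""
    nodes = set(network.nodes)
    by_herb: dict[str, set[str]] = {}
    order: list[str] = []
    for rec in records:
        if rec.herb not in by_herb:
            by_herb[rec.herb] = set()
            order.append(rec.herb)
        by_herb[rec.herb].add(rec.target)
    sets = []
    for herb in order:
        kept = by_herb[herb] & nodes
        dropped = sorted(by_herb[herb] - nodes)
        if report is not None and dropped:
            report.dropped_genes[herb] = dropped
        if not kept:
            if report is not None:
                report.excluded_sets.append(herb)
            log.warning("herb %r excluded: no targets present in the network", herb)
            continue
        sets.append(SeedGeneSet(name=herb, category="herb", genes=frozenset(kept)))
    return sets


def read_gmt(path: str | Path) -> AnnotationCollection:
    """Read a GMT collection: name <TAB> description <TAB> gene1 <TAB> ...."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line needs >=3 columns")
        name = cols[0].strip()
        if name in sets:
            raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
        genes = frozenset(normalize_gene(g) for g in cols[2:] if g.strip())
        if not genes:
            raise ParseError(f"{path}:{lineno}: set {name!r} has no genes")
        sets[name] = genes
        descriptions[name] = cols[1].strip()
    if not sets:
        raise InputError(f"{path}: GMT file contains no sets")
    return AnnotationCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: AnnotationCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")
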