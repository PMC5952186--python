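#!/usr/bin/env python
"""Fisher module-enrichment of every seed gene group.

Scores every (module, seed group) pair — individual diseases, symptoms,
herbs, and their union aggregates — with a one-sided Fisher exact test
against the network universe, writes the full enrichment table and the
per-module positivity counts, and reports which modules carry signal.
"""

from pathlib import Path

import pandas as pd

from netpharm.community import detect_modules
from netpharm.enrichment import enrich_all
from netpharm.io import herb_seed_sets, read_herb_table, read_network, read_seed_sets
from netpharm.prioritize import enrichment_frame
from netpharm.types import SeedGeneSet

SEED = 0
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    inputs = RESULTS / "inputs"
    graph, _ = read_network(inputs / "edge_list.tsv")
    groups, _ = read_seed_sets(inputs / "seed_sets.tsv", graph)
    herb_records, _ = read_herb_table(inputs / "herb_table.tsv")
    herbs = herb_seed_sets(herb_records, graph)
    if herbs:
        union = frozenset().union(*(h.genes for h in herbs))
        herbs.append(SeedGeneSet("Herbs", "aggregate-herbs", union))

    partition = detect_modules(graph, seed=SEED)
    records, counts = enrich_all(partition, list(groups) + herbs,
                                 frozenset(graph.nodes), alpha=0.05)

    enrichment_frame(records).to_csv(RESULTS / "enrichment.tsv", sep="\t", index=False)
    pd.DataFrame([{"module_label": c.module_label, "n_positive": c.n_positive}
                  for c in counts]).to_csv(RESULTS / "positivity.tsv",
                                           sep="\t", index=False)

    print(f"{len(records)} (module, group) pairs tested at alpha = 0.05")
    for c in counts:
        print(f"  {c.module_label}: {c.n_positive} positive results")
    best = min(records, key=lambda r: r.p_value)
    print(f"strongest enrichment: {best.group_name} in {best.module_label} "
          f"(k={best.k}, p={best.p_value:.3g}, fold={best.proportion:.2f})")


if __name__ == "__main__":
    main()
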