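# Methods

## Scope and model

`netpharm` implements the module-based network-pharmacology inference
chain: a PPI network is partitioned into topological modules; curated seed
gene groups (individual co-morbid diseases, individual symptoms, individual
herbs, and the three union aggregates) are tested for over-representation
in each module; herb protein targets are ranked by shortest-path proximity
to the selected modules and to the phenotype unions; and targets passing
the proximity conjunction become candidate key targets. The chain treats
the interactome as an undirected, unweighted simple graph and all gene
identifiers as plain uppercase symbols — no alias mapping, no evidence
weighting, no component filtering (disconnection is handled by explicit
reachability accounting instead).

## Module detection

Default algorithm: greedy (agglomerative) modularity maximization of the
Newman quality

Q = Σ_c ( e_c/m − (d_c/2m)² ),

as implemented by networkx's Clauset–Newman–Moore routine; asynchronous
label propagation is available as an alternative (`method=
label-propagation`, seeded). The input graph is canonicalized — nodes and
edges sorted — before detection, so the partition depends only on the
network's node and edge *sets*, never on file order; for a fixed
(network, method, seed, min_size) the output is bit-identical. Greedy
modularity itself is deterministic; the seed only affects label
propagation.

Modules smaller than `min_size` (default 3) are folded into the reserved
label `M0-unassigned` and skipped by enrichment: a 1–2 gene module cannot
produce a meaningful 2×2 overlap test. Real modules are labelled M1..Mk in
decreasing size, ties broken by the lexicographically smallest member, so
labels are stable and human-scannable. The stored modularity score is Q of
the raw detected partition (before the fold). Module labels are
regenerated per run; no correspondence with any published module numbering
is attempted, since that depends on the interactome version.

## Enrichment

For module M, group S and universe N (the loaded network's gene set — the
natural background here, since both modules and path analysis live on the
network), the p-value is the upper hypergeometric tail P(X ≥ k) computed
via `scipy.stats.hypergeom.sf`; the test is one-sided (enrichment only:
depletion is not a relevant outcome for this question, and the fold values
of interest are all > 1). Fold enrichment ("proportion") is
(k/|M|)/(|S|/N), reported as 0 when k = 0 so the output table stays total.
Positivity is the raw p < α rule with α = 0.05 by default; Benjamini–
Hochberg FDR across all tested pairs is available (`correction: bh`) but
off by default to match the uncorrected convention of this analysis
style. Plain Fisher is used for the generic GMT-based over-representation
step as well; no EASE-style k−1 adjustment, no GO-graph propagation.

The exhaustive benchmark (`tests/test_acceptance.py`) checks every 2×2
table with universe ≤ 40 against exact rational-arithmetic tail
enumeration; agreement is ≤ 1e-12 absolute (measured ≈ 3e-16).

## Shortest-path proximity

Distances are exact unweighted shortest paths computed by Dijkstra with
unit edge weights (validated against BFS and Floyd–Warshall, with which it
must and does coincide exactly). Per (target, group) pair the summary is
min/max/mean over the group's *reachable* members; unreachable members are
excluded from all three statistics and reported via `n_total −
n_reachable` rather than folded in as infinite penalties — averages stay
finite and interpretable. A source belonging to the group contributes its
own distance 0 (the worked-example tables' `Min_sp = 0` rows force this
convention). The key-target rule is strict: `avg_sp < 3` with threshold 3
by default — strictness matters, since the reference CRH/Symptoms row sits
at 2.998833 and is called key, while exactly 3.0 is not. Pairs with no
reachable member are flagged undefined, logged, and never called key.

## Prioritization

Modules are ranked by positivity count (number of seed groups with p < α).
The default selection rule is `top_n = 2`, mirroring the worked example's
two leading modules; modules with zero positives never qualify, so the
selection can be empty (a warning, not an error) and on clean planted
instances only the signal-bearing module is selected. `min_positive` is
available when an absolute cutoff is preferred. A target is a candidate
when it is key for **at least one** selected module (requiring all selected
modules would be stricter than the analysis this mirrors, where no target
was key for both leading modules) AND for the aggregate-diseases group AND
the aggregate-symptoms group. Candidates are ranked by mean `avg_sp`
ascending: closer is stronger.

## Synthetic data

The generator produces the statistical structure the analysis assumes,
with ground truth:

* **Network** — stochastic block model with `n_communities` near-equal
  blocks, within/between edge probabilities `p_in`/`p_out`. Defaults
  (n = 120, 4 communities, p_in = 0.3, p_out = 0.01) give strong but not
  degenerate contrast: average within-degree ≈ 9, a few dozen
  between-community edges, typical between-community distances 3–4. Block
  models are a deliberate simplification — they lack the heavy-tailed
  degree distribution, hubs, and date/party structure of real
  interactomes, so passing recovery benchmarks here demonstrates
  correctness of the inference machinery, not performance on real PPI
  data.
* **Seed groups** — the number of in-module members is drawn
  Binomial(group_size, fold·m/n), then members are sampled without
  replacement inside/outside the module, making the expected overlap
  exactly fold·(m/n)·group_size. Defaults (group 15, fold 4, module
  30/120) put the whole group in the module — the maximal-contrast regime;
  fold 1 reproduces uniform placement. Infeasible folds raise an error
  reporting the maximum feasible value.
* **Targets** — the planted proximal target `TGT1` attaches to
  ⌈attach_fraction·m⌉ uniformly chosen module nodes (default 50%);
  `plant_random_target` provides the degree-matched null wired uniformly
  over the whole network. The bundled decoy targets `DEC1`/`DEC2` instead
  hang off 1–2 nodes of *non-planted* communities, so they fail the
  proximity conjunction by a comfortable margin — the bundle is built so
  the correct answer is unambiguous, which is what an end-to-end
  recovery test needs.

All generators take explicit seeds (numpy `default_rng`) and regeneration
is byte-identical.

## Reference tables

`netpharm.reference_tables` transcribes the printed worked-example rows
(29 module-enrichment rows across six modules; six shortest-path rows for
CRH and NPPA). Their upstream inputs (interactome and database versions)
are unavailable, so these values are *inputs*, not recomputed outputs:
they exercise the positivity filter and the key-target conjunction, whose
outputs (12/8/4/2/2/1 positives; CRH + NPPA) must match the printed
summary lines exactly.

## Numerical and formatting choices

* p-values: scipy's hypergeometric survival function, clipped to [0, 1];
  no log-space arithmetic is needed at these table sizes.
* `avg_sp` is written with 6 decimal places, p-values with `%.6g`; all
  report tables are written with sorted, stable ordering so a rerun with
  the same config and seed is byte-identical (the determinism contract is
  tested).
* Undefined path summaries serialize as `NA`.
* Problem sizes in the benchmark suite (100 replicates of the 120-node
  planted model; 100 random graphs of 200 nodes for the distance oracle;
  universe ≤ 40 for the exhaustive Fisher sweep) are chosen so the full
  suite completes in well under a minute while the binomial/recovery
  margins stay wide.

## Known limitations

* Greedy modularity has a resolution limit and is only one member of the
  community-detection family; on real interactomes different algorithms
  (or resolutions) yield different module sets, and this package makes no
  claim of reproducing any particular published partition.
* The enrichment universe is the network's gene set; enrichment against a
  genome-wide or database background would shift p-values.
* Unweighted shortest paths ignore interaction confidence; no random-walk
  or diffusion proximity variants are provided.
* The synthetic generator does not emulate curation noise (synonyms,
  species contamination) or scale-free topology.
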