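"""Fisher enrichment: closed forms, enumeration oracle, monotonicity, ORA."""

import math
import random

import numpy as np
import pytest

from netpharm.enrichment import (
    enrich_all,
    fisher_enrichment,
    fold_enrichment,
    hypergeom_tail,
    ora,
)
from netpharm.types import (
    AnnotationCollection,
    ConsistencyError,
    InputError,
    ModulePartition,
    SeedGeneSet,
)

from oracles import exact_hypergeom_tail


def genes(prefix, n):
    return [f"{prefix}{i:03d}" for i in range(n)]


def record_for(universe_n, module_n, group_n, k, alpha=0.05):
    """Build disjointly-prefixed gene sets realizing a given 2x2 table."""
    assert k <= min(module_n, group_n)
    assert module_n + group_n - k <= universe_n
    shared = genes("S", k)
    mod_only = genes("M", module_n - k)
    grp_only = genes("G", group_n - k)
    rest = genes("R", universe_n - module_n - group_n + k)
    universe = frozenset(shared + mod_only + grp_only + rest)
    module = frozenset(shared + mod_only)
    group = SeedGeneSet("grp", "disease", frozenset(shared + grp_only))
    return fisher_enrichment(module, group, universe, alpha=alpha, module_label="M1")


class TestFisher:
    def test_full_overlap_closed_form(self):
        rec = record_for(10, 5, 5, 5)
        assert rec.p_value == pytest.approx(1 / math.comb(10, 5), abs=1e-15)
        assert rec.positive

    def test_zero_overlap_p_is_one(self):
        rec = record_for(20, 5, 5, 0)
        assert rec.p_value == 1.0
        assert not rec.positive
        assert rec.proportion == 0.0

    def test_tail_sum_40_8_10_5(self):
        rec = record_for(40, 8, 10, 5)
        expect = sum(
            math.comb(10, i) * math.comb(30, 8 - i) / math.comb(40, 8)
            for i in range(5, 9)
        )
        assert rec.p_value == pytest.approx(expect, abs=1e-12)

    def test_random_tables_match_enumeration_oracle(self):
        rng = random.Random(23)
        for _ in range(200):
            n = rng.randint(2, 40)
            m = rng.randint(1, n)
            g = rng.randint(1, n)
            k = rng.randint(max(0, m + g - n), min(m, g))
            rec = record_for(n, m, g, k)
            assert rec.p_value == pytest.approx(
                exact_hypergeom_tail(k, n, g, m), abs=1e-12
            )

    def test_monotone_nonincreasing_in_k(self):
        ps = [float(hypergeom_tail(k, 50, 12, 15)) for k in range(0, 13)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_proportion_identities(self):
        rec = record_for(40, 10, 8, 2)  # k*N == m*g -> proportion exactly 1
        assert rec.proportion == pytest.approx(1.0, abs=1e-12)
        above = record_for(40, 10, 8, 5)
        assert above.proportion > 1 and above.k * 40 > 10 * 8

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1])
    def test_alpha_bounds(self, alpha):
        with pytest.raises(InputError):
            record_for(10, 3, 3, 1, alpha=alpha)

    def test_empty_inputs_rejected(self):
        universe = frozenset(genes("U", 5))
        group = SeedGeneSet("g", "disease", frozenset(list(universe)[:2]))
        with pytest.raises(InputError):
            fisher_enrichment(frozenset(), group, universe)

    def test_containment_enforced(self):
        universe = frozenset(genes("U", 5))
        group = SeedGeneSet("g", "disease", frozenset({"ALIEN"}))
        with pytest.raises(ConsistencyError):
            fisher_enrichment(universe, group, universe)

    def test_permutation_positive_rate_bounded(self):
        """Uniform random groups are positive at alpha=0.05 in <= 8% of draws."""
        universe = sorted(genes("U", 100))
        module = frozenset(universe[:20])
        rng = np.random.default_rng(2024)
        hits = 0
        n_draws = 1000
        for _ in range(n_draws):
            draw = frozenset(rng.choice(universe, size=10, replace=False))
            rec = fisher_enrichment(
                module, SeedGeneSet("g", "disease", draw), frozenset(universe)
            )
            hits += rec.positive
        assert hits / n_draws <= 0.08


def two_module_partition():
    assign = {g: "M1" for g in genes("A", 6)}
    assign.update({g: "M2" for g in genes("B", 6)})
    return ModulePartition(assignment=assign, labels=["M1", "M2"],
                           modularity_score=0.3), frozenset(assign)


class TestEnrichAll:
    def test_cross_product_count_and_order(self):
        part, universe = two_module_partition()
        groups = [SeedGeneSet(f"g{i}", "disease", frozenset(genes("A", 3)))
                  for i in range(3)]
        records, counts = enrich_all(part, groups, universe)
        assert len(records) == 6
        assert [r.module_label for r in records] == ["M1"] * 3 + ["M2"] * 3
        # within a module, ascending p
        ps = [r.p_value for r in records[:3]]
        assert ps == sorted(ps)

    def test_contained_group_beats_disjoint_module(self):
        part, universe = two_module_partition()
        grp = SeedGeneSet("inA", "disease", frozenset(genes("A", 4)))
        records, _ = enrich_all(part, [grp], universe)
        by_mod = {r.module_label: r for r in records}
        assert by_mod["M1"].p_value < by_mod["M2"].p_value
        assert by_mod["M1"].positive

    def test_positivity_counts_match_flags(self):
        part, universe = two_module_partition()
        groups = [SeedGeneSet("inA", "disease", frozenset(genes("A", 4))),
                  SeedGeneSet("mix", "symptom",
                              frozenset(genes("A", 2) + genes("B", 2)))]
        records, counts = enrich_all(part, groups, universe)
        tally = {c.module_label: c.n_positive for c in counts}
        for lab in ("M1", "M2"):
            assert tally[lab] == sum(
                r.positive for r in records if r.module_label == lab
            )

    def test_unassigned_module_skipped(self):
        part, universe = two_module_partition()
        part.assignment["STRAY"] = "M0-unassigned"
        universe = universe | {"STRAY"}
        grp = SeedGeneSet("g", "disease", frozenset(genes("A", 3)))
        records, _ = enrich_all(part, [grp], universe)
        assert {r.module_label for r in records} == {"M1", "M2"}

    def test_bh_correction_never_adds_positives(self):
        part, universe = two_module_partition()
        groups = [SeedGeneSet("inA", "disease", frozenset(genes("A", 4))),
                  SeedGeneSet("mix", "symptom",
                              frozenset(genes("A", 2) + genes("B", 2)))]
        raw, _ = enrich_all(part, groups, universe)
        bh, _ = enrich_all(part, groups, universe, correction="bh")
        assert sum(r.positive for r in bh) <= sum(r.positive for r in raw)

    def test_no_groups_is_error(self):
        part, universe = two_module_partition()
        with pytest.raises(InputError):
            enrich_all(part, [], universe)


class TestOra:
    def test_exact_set_ranks_first(self):
        a = frozenset(genes("A", 6))
        b = frozenset(genes("B", 6))
        coll = AnnotationCollection(sets={"SA": a, "SB": b})
        records, skipped = ora(a, coll, a | b)
        assert records[0].group_name == "SA"
        assert records[0].p_value < records[1].p_value
        assert skipped == []

    def test_disjoint_set_skipped(self):
        a = frozenset(genes("A", 6))
        coll = AnnotationCollection(sets={"SA": a, "SX": frozenset({"ALIEN"})})
        records, skipped = ora(a, coll, a)
        assert skipped == ["SX"] and len(records) == 1

    def test_random_sets_match_oracle(self):
        rng = random.Random(31)
        universe = genes("U", 200)
        query = frozenset(rng.sample(universe, 25))
        sets = {
            f"S{i:02d}": frozenset(rng.sample(universe, rng.randint(5, 40)))
            for i in range(20)
        }
        records, _ = ora(query, AnnotationCollection(sets=sets), frozenset(universe))
        assert len(records) == 20
        for rec in records:
            members = sets[rec.group_name]
            k = len(query & members)
            expect = exact_hypergeom_tail(k, 200, len(members), len(query))
            assert rec.p_value == pytest.approx(expect, abs=1e-12)

    def test_empty_query_rejected(self):
        coll = AnnotationCollection(sets={"SA": frozenset({"A"})})
        with pytest.raises(InputError):
            ora(frozenset(), coll, frozenset({"A"}))


def test_planted_enrichment_minimizes_p():
    """A group drawn at fold 4 from the planted module attains the minimum p."""
    from netpharm.simulate import SyntheticSpec, generate_seed_group

    spec = SyntheticSpec(seed=99)
    labels = {f"G{i:06d}": i % 4 for i in range(120)}
    spec = SyntheticSpec(seed=99, planted_module=0)
    grp = generate_seed_group(labels, spec)
    universe = frozenset(labels)
    ps = {}
    for c in range(4):
        mod = frozenset(g for g, cc in labels.items() if cc == c)
        ps[c] = fisher_enrichment(mod, grp, universe).p_value
    assert min(ps, key=ps.get) == 0


def test_fold_enrichment_zero_convention():
    assert fold_enrichment(0, 10, 5, 100) == 0.0
    assert fold_enrichment(2, 10, 5, 100) == pytest.approx((2 / 10) / (5 / 100))
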