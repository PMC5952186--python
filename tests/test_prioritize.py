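"""Key-module selection, candidate intersection, and the pipeline driver."""

import itertools
import math
import random
from pathlib import Path

import pytest

from netpharm.prioritize import (
    PipelineConfig,
    intersect_key_targets,
    pathway_key_overlap,
    run_pipeline,
    select_key_modules,
)
from netpharm.simulate import PLANTED_TARGET
from netpharm.types import (
    AnnotationCollection,
    InputError,
    KeyModuleSelection,
    KeyTargetCall,
    PositivityCount,
)


def counts(**kw):
    return [PositivityCount(module_label=k, n_positive=v) for k, v in kw.items()]


class TestSelect:
    def test_top_n_two(self):
        sel = select_key_modules(counts(M1=12, M2=8, M3=4), rule="top_n", param=2)
        assert sel.selected == ["M1", "M2"]

    def test_min_positive_empty_selection_is_warning_not_error(self):
        sel = select_key_modules(counts(M1=1), rule="min_positive", param=2)
        assert sel.selected == []

    def test_top_n_skips_zero_positive_modules(self):
        sel = select_key_modules(counts(M1=3, M2=0, M3=0), rule="top_n", param=2)
        assert sel.selected == ["M1"]

    def test_random_counts_match_sort_and_slice_oracle(self):
        rng = random.Random(41)
        for _ in range(50):
            vals = {f"M{i + 1}": rng.randrange(0, 10) for i in range(8)}
            param = rng.randint(1, 5)
            sel = select_key_modules(counts(**vals), rule="top_n", param=param)
            oracle = sorted(
                (m for m, v in vals.items() if v > 0),
                key=lambda m: (-vals[m], int(m[1:])),
            )[:param]
            assert sel.selected == oracle

    def test_tie_broken_by_label(self):
        sel = select_key_modules(counts(M2=5, M1=5), rule="top_n", param=1)
        assert sel.selected == ["M1"]

    def test_bad_rule_and_param(self):
        with pytest.raises(InputError):
            select_key_modules(counts(M1=1), rule="bottom_n", param=1)
        with pytest.raises(InputError):
            select_key_modules(counts(M1=1), param=0)
        with pytest.raises(InputError):
            select_key_modules([], param=1)


def call(source, group_name, category, avg, threshold=3.0):
    return KeyTargetCall(
        source=source,
        group_name=group_name,
        group_category=category,
        avg_sp=avg,
        is_key=(not math.isnan(avg)) and avg < threshold,
        threshold=threshold,
    )


def selection(*labels):
    return KeyModuleSelection(selected=list(labels), rule="top_n(2)")


class TestIntersect:
    def test_full_conjunction_included(self):
        calls = [
            call("CRH", "M1", "module", 1.7),
            call("CRH", "Diseases", "aggregate-diseases", 2.94),
            call("CRH", "Symptoms", "aggregate-symptoms", 2.99),
        ]
        cands = intersect_key_targets(calls, selection("M1"))
        assert [c.gene for c in cands] == ["CRH"]
        assert cands[0].modules_hit == ["M1"]

    def test_failed_symptom_leg_excluded(self):
        calls = [
            call("X", "M1", "module", 1.7),
            call("X", "Diseases", "aggregate-diseases", 2.0),
            call("X", "Symptoms", "aggregate-symptoms", 3.4),
        ]
        assert intersect_key_targets(calls, selection("M1")) == []

    def test_unselected_module_does_not_count(self):
        calls = [
            call("X", "M9", "module", 1.0),
            call("X", "Diseases", "aggregate-diseases", 1.0),
            call("X", "Symptoms", "aggregate-symptoms", 1.0),
        ]
        assert intersect_key_targets(calls, selection("M1")) == []

    def test_missing_aggregates_rejected(self):
        calls = [call("X", "M1", "module", 1.0)]
        with pytest.raises(InputError, match="aggregate"):
            intersect_key_targets(calls, selection("M1"))

    def test_sorted_by_mean_avg_sp(self):
        def target(name, a):
            return [
                call(name, "M1", "module", a),
                call(name, "Diseases", "aggregate-diseases", a),
                call(name, "Symptoms", "aggregate-symptoms", a),
            ]

        cands = intersect_key_targets(target("SLOW", 2.5) + target("FAST", 1.0),
                                      selection("M1"))
        assert [c.gene for c in cands] == ["FAST", "SLOW"]

    def test_randomized_calls_match_boolean_oracle(self):
        rng = random.Random(7)
        for _ in range(30):
            sel = selection("M1", "M2")
            calls, truth = [], {}
            for t in [f"T{i}" for i in range(6)]:
                avg = {
                    "M1": rng.uniform(1, 5),
                    "M2": rng.uniform(1, 5),
                    "Diseases": rng.uniform(1, 5),
                    "Symptoms": rng.uniform(1, 5),
                }
                calls += [
                    call(t, "M1", "module", avg["M1"]),
                    call(t, "M2", "module", avg["M2"]),
                    call(t, "Diseases", "aggregate-diseases", avg["Diseases"]),
                    call(t, "Symptoms", "aggregate-symptoms", avg["Symptoms"]),
                ]
                truth[t] = (
                    (avg["M1"] < 3 or avg["M2"] < 3)
                    and avg["Diseases"] < 3
                    and avg["Symptoms"] < 3
                )
            got = {c.gene for c in intersect_key_targets(calls, sel)}
            assert got == {t for t, ok in truth.items() if ok}

    def test_conjunction_soundness(self):
        """Every stored supporting avg_sp of a candidate is below threshold."""
        calls = [
            call("CRH", "M1", "module", 1.7),
            call("CRH", "Diseases", "aggregate-diseases", 2.94),
            call("CRH", "Symptoms", "aggregate-symptoms", 2.99),
        ]
        for cand in intersect_key_targets(calls, selection("M1")):
            assert all(a < 3.0 for _, a in cand.supporting)


class TestPathwayOverlap:
    def test_containment(self):
        module = frozenset({"A", "B", "C", "D"})
        keys = frozenset({"A", "B"})
        coll = AnnotationCollection(sets={"PW": module})
        rows = pathway_key_overlap(coll, module, keys)
        assert rows == [("PW", 4, 2)]

    def test_disjoint_yields_zeros(self):
        coll = AnnotationCollection(sets={"PW": frozenset({"X", "Y"})})
        rows = pathway_key_overlap(coll, frozenset({"A"}), frozenset({"A"}))
        assert rows == [("PW", 0, 0)]

    def test_random_sets_match_set_algebra(self):
        rng = random.Random(3)
        genes = [f"G{i:02d}" for i in range(50)]
        module = frozenset(rng.sample(genes, 20))
        keys = frozenset(rng.sample(sorted(module), 6))
        sets = {f"S{i}": frozenset(rng.sample(genes, rng.randint(3, 25)))
                for i in range(10)}
        rows = pathway_key_overlap(AnnotationCollection(sets=sets), module, keys)
        for name, n_pw, n_key in rows:
            assert n_pw == len(sets[name] & module)
            assert n_key == len(sets[name] & module & keys)
            assert n_key <= n_pw


class TestPipeline:
    def make_config(self, bundle_dir, seed=3):
        return PipelineConfig(
            network=bundle_dir["network"],
            seed_sets=bundle_dir["seed_sets"],
            herb_table=bundle_dir["herb_table"],
            annotations=bundle_dir["annotations"],
            seed=seed,
        )

    def test_bundle_contains_all_reports(self, bundle_dir, tmp_path):
        bundle = run_pipeline(self.make_config(bundle_dir), out_dir=tmp_path)
        expect = {"modules.tsv", "module_summary.tsv", "enrichment.tsv",
                  "positivity.tsv", "path_summaries.tsv", "candidates.tsv",
                  "manifest.yaml"}
        assert expect <= {p.name for p in tmp_path.iterdir()}
        header = (tmp_path / "path_summaries.tsv").read_text().splitlines()[0]
        assert header.split("\t") == ["source", "group_name", "min_sp", "max_sp",
                                      "avg_sp", "n_reachable", "n_total", "is_key"]

    def test_planted_target_is_sole_candidate(self, bundle_dir, tmp_path):
        bundle = run_pipeline(self.make_config(bundle_dir))
        assert [c.gene for c in bundle.candidates] == [PLANTED_TARGET]

    def test_rerun_is_byte_identical(self, bundle_dir, tmp_path):
        cfg = self.make_config(bundle_dir)
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        run_pipeline(cfg, out_dir=out1)
        run_pipeline(cfg, out_dir=out2)
        files = sorted(p.name for p in out1.iterdir())
        assert files == sorted(p.name for p in out2.iterdir())
        for name in files:
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes(), name

    def test_stage_error_carries_stage_name(self, bundle_dir):
        cfg = self.make_config(bundle_dir)
        cfg.network = "does/not/exist.tsv"
        with pytest.raises(InputError, match=r"\[read-network\]"):
            run_pipeline(cfg)

    def test_config_yaml_round_trip(self, bundle_dir, tmp_path):
        import yaml

        cfg = self.make_config(bundle_dir)
        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump(cfg.to_dict()))
        assert PipelineConfig.from_yaml(p) == cfg

    def test_unknown_config_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("network: x\nseed_sets: y\nherb_table: z\nbogus: 1\n")
        with pytest.raises(InputError, match="bogus"):
            PipelineConfig.from_yaml(p)
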