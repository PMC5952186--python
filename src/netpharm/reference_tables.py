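"""Worked-example reference rows from a published herbal-formula analysis.

These rows transcribe the printed summary tables of a coronary-heart-disease
network-pharmacology study of the LianXia NingXin (LXNX) herb formula: the
module-enrichment positive results for modules M146 / M203 / M194 / M195 /
M204 / M95, and the shortest-path summaries for the two key herb targets CRH
and NPPA. They serve as regression fixtures for the two decision rules of
the pipeline:

* positivity rule — an enrichment row is positive when p < 0.05; the
  per-module positive counts must reproduce the printed summary lines
  (M146: 12, M203: 8, M194: 4, M195: 2, M204: 2, M95: 1);
* key-target rule — a source is a strongly-connecting key target of a gene
  group when its mean shortest path is strictly below 3; applying the
  module AND diseases AND symptoms conjunction to the path rows must yield
  exactly CRH and NPPA as candidate targets.

The underlying interactome and database versions are unavailable, so these
values cannot be recomputed from raw inputs; they are kept verbatim as the
ground truth the filters are checked against.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class ReferenceEnrichmentRow:
    """One enrichment row: module, seed group, overlap, p, fold proportion."""

    module_label: str
    group_name: str
    k: int
    p_value: float
    proportion: float

    @property
    def positive(self) -> bool:
        return self.p_value < 0.05


@dataclass(frozen=True)
class ReferencePathRow:
    """One shortest-path summary row for a source target and gene group."""

    source: str
    group_name: str
    min_sp: int
    max_sp: int
    avg_sp: float

    @property
    def is_key(self) -> bool:
        return self.avg_sp < 3.0


_T2 = [
    # module, group, k, p, proportion
    ("M146", "Anxiety (D)", 13, 2.90e-06, 4.770082),
    ("M146", "Chest pain (S)", 25, 0.0221, 1.38308),
    ("M146", "Dizziness (S)", 28, 0.012776, 1.429755),
    ("M146", "Insomnia (S)", 8, 0.00495, 2.877702),
    ("M146", "Palpitations (S)", 12, 1.27e-09, 10.55632),
    ("M146", "Shortness of breath (S)", 5, 0.033574, 2.538544),
    ("M146", "Thirst (S)", 23, 5.05e-16, 9.163804),
    ("M146", "Pinellia Tuber(Ban Xia)", 25, 1.40e-05, 2.487102983),
    ("M146", "Poria coco(Fu Ling)", 8, 0.041464852, 1.821802935),
    ("M146", "Diseases", 14, 0.000434, 3.083373),
    ("M146", "Herbs", 34, 0.002613, 1.809648),
    ("M146", "Symptoms", 57, 9.68e-06, 2.129997),
    ("M203", "Arrhythmia (D)", 3, 0.005047, 8.311160088),
    ("M203", "Autonomic dysfunction (D)", 1, 0.015491, 63.71889401),
    ("M203", "Chest pain (S)", 8, 0.013648, 2.270036),
    ("M203", "Dizziness (S)", 9, 0.00725, 2.357119),
    ("M203", "Palpitations (S)", 2, 0.019188, 9.023954),
    ("M203", "Thirst (S)", 3, 0.011237, 6.130623),
    ("M203", "Diseases", 5, 0.002451, 6.064949),
    ("M203", "Symptoms", 13, 0.006585, 2.732289),
    ("M194", "Chest pain (S)", 9, 0.000671, 3.298646),
    ("M194", "Dizziness (S)", 9, 0.001176, 3.044612),
    ("M194", "Insomnia (S)", 3, 0.007411, 7.149291),
    ("M194", "Symptoms", 12, 0.001491, 3.783921),
    ("M195", "Chest pain (S)", 4, 0.049971, 2.513254),
    ("M195", "Symptoms", 7, 0.014961, 3.779208),
    ("M204", "Cardiac sympathetic remodeling (D)", 1, 0.049286, 19.47464789),
    ("M204", "Dizziness (S)", 24, 0.025127, 1.37222),
    ("M95", "Chest pain (S)", 3, 0.020438, 4.398194),
]

#: printed per-module positive-result summary counts
REFERENCE_POSITIVE_COUNTS = {
    "M146": 12,
    "M203": 8,
    "M194": 4,
    "M195": 2,
    "M204": 2,
    "M95": 1,
}

_T4 = [
    # source, group, min, max, avg
    ("CRH", "Diseases", 0, 7, 2.943452),
    ("CRH", "Symptoms", 0, 9, 2.998833),
    ("CRH", "M146", 0, 4, 1.686667),
    ("NPPA", "Diseases", 0, 6, 2.705357),
    ("NPPA", "Symptoms", 0, 9, 2.740698),
    ("NPPA", "M203", 0, 3, 1.548387),
]


def reference_enrichment_rows() -> list[ReferenceEnrichmentRow]:
    return [ReferenceEnrichmentRow(*row) for row in _T2]


def reference_path_rows() -> list[ReferencePathRow]:
    return [ReferencePathRow(*row) for row in _T4]


def reference_positivity_counts() -> dict[str, int]:
    """Apply the p < 0.05 positivity rule to the reference enrichment rows."""
    counts: dict[str, int] = {}
    for row in reference_enrichment_rows():
        counts.setdefault(row.module_label, 0)
        if row.positive:
            counts[row.module_label] += 1
    return counts


def reference_candidate_targets(threshold: float = 3.0) -> list[str]:
    """Apply the avg < threshold key-target conjunction to the path rows.

    A source qualifies when it is key for its module group AND for the
    Diseases aggregate AND for the Symptoms aggregate.
    """
    by_source: dict[str, dict[str, float]] = {}
    for row in reference_path_rows():
        by_source.setdefault(row.source, {})[row.group_name] = row.avg_sp
    out = []
    for source in sorted(by_source):
        groups = by_source[source]
        module_ok = any(
            avg < threshold for name, avg in groups.items() if name.startswith("M")
        )
        if (
            module_ok
            and groups.get("Diseases", float("inf")) < threshold
            and groups.get("Symptoms", float("inf")) < threshold
        ):
            out.append(source)
    return out


def enrichment_table() -> pd.DataFrame:
    """Reference enrichment rows as a DataFrame (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "module_label": r.module_label,
                "group_name": r.group_name,
                "k": r.k,
                "p_value": repr(r.p_value),
                "proportion": repr(r.proportion),
            }
            for r in reference_enrichment_rows()
        ]
    )


def path_table() -> pd.DataFrame:
    """Reference path rows as a DataFrame (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "source": r.source,
                "group_name": r.group_name,
                "min_sp": r.min_sp,
                "max_sp": r.max_sp,
                "avg_sp": f"{r.avg_sp:.6f}",
            }
            for r in reference_path_rows()
        ]
    )
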