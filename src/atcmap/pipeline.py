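"""End-to-end orchestration: partition, group, match, validate, report.

The assessment pipeline mirrors a 4-step workflow for free-text
prescription data: (1) partition records into structured (catalog-picked,
ATC present) and unstructured; (2) group the unstructured free texts,
exclude non-medication orders by rule, and run the three matching
algorithms over the most frequent texts; (3) round-trip a validation
workbook through manual (or simulated) review; (4) merge everything back
and report structuredness overall, by ATC level-1 group and by level-5
ingredient.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import pandas as pd

from .atc import (
    AtcCode,
    DrugCatalog,
    GroupedEntry,
    PrescriptionRecord,
    ValidationRecord,
)
from .io import DialectConfig, read_workbook, write_workbook
from .matchers import run_cascade
from .rules import (
    DEFAULT_RULES,
    ConcordanceFlags,
    ExclusionRule,
    classify_non_medication,
    concordance,
)

__all__ = [
    "StructurednessSummary",
    "partition",
    "GroupingResult",
    "group_unstructured",
    "topN_coverage",
    "make_workbook",
    "export_validation_workbook",
    "import_validation_workbook",
    "FinalAssessment",
    "final_assessment",
    "run_pipeline",
    "PipelineResult",
    "round_pct",
]


def round_pct(x: float, ndigits: int = 2) -> float:
    """Percentage rounding, half away from zero at ``ndigits`` decimals."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


@dataclass(frozen=True)
class StructurednessSummary:
    """Counts (and derived percentages) of where every prescription landed.

    ``n_structured + n_unstructured == n_total`` and
    ``n_validated + n_not_validated == n_total``; the validated side is
    structured records plus unstructured records resolved to an ATC code,
    excluded as non-medication (``nomed``), or flagged unspecific.
    """

    n_total: int
    n_structured: int
    n_unstructured: int
    n_excluded_nomed: int = 0
    n_unspec: int = 0
    n_validated_unstructured: int = 0
    n_not_validated: int = 0

    @property
    def n_validated(self) -> int:
        return (
            self.n_structured
            + self.n_validated_unstructured
            + self.n_excluded_nomed
            + self.n_unspec
        )

    def _pct(self, n: int) -> float:
        return round_pct(100.0 * n / self.n_total) if self.n_total else 0.0

    @property
    def pct_structured(self) -> float:
        return self._pct(self.n_structured)

    @property
    def pct_unstructured(self) -> float:
        return self._pct(self.n_unstructured)

    @property
    def pct_validated(self) -> float:
        return self._pct(self.n_validated)

    @property
    def pct_not_validated(self) -> float:
        return self._pct(self.n_not_validated)


def partition(
    records: Sequence[PrescriptionRecord],
) -> tuple[list[PrescriptionRecord], list[PrescriptionRecord], StructurednessSummary]:
    """Split records by the structured flag; disjoint and exhaustive."""
    structured = [r for r in records if r.structured]
    unstructured = [r for r in records if not r.structured]
    summary = StructurednessSummary(
        n_total=len(records),
        n_structured=len(structured),
        n_unstructured=len(unstructured),
        n_not_validated=len(unstructured),
    )
    return structured, unstructured, summary


@dataclass
class GroupingResult:
    """Grouped unique free texts plus the rule-excluded ones.

    ``sum(g.frequency for g in groups) + n_excluded == number of
    unstructured records grouped`` — exclusion happens before grouping and
    is counted, never silently dropped.
    """

    groups: list
    excluded: dict  # medication text -> (rule_id, frequency)
    n_input: int

    @property
    def n_excluded(self) -> int:
        return sum(freq for _rule, freq in self.excluded.values())


def group_unstructured(
    unstructured: Sequence[PrescriptionRecord],
    rules: Sequence[ExclusionRule] = DEFAULT_RULES,
) -> GroupingResult:
    """Group unstructured records by their exact raw MEDICATION string.

    The grouping key is case-sensitive and unnormalized (variants like
    "NaCl 0.9%" and "NaCL 0.9%" are distinct entries, as they are distinct
    rows in real validation data).  Rule-excluded texts are removed first
    and counted; groups come back sorted by frequency descending, then key
    ascending.
    """
    counts = Counter(r.medication for r in unstructured)
    excluded: dict[str, tuple[str, int]] = {}
    groups: list[GroupedEntry] = []
    for text, freq in counts.items():
        rule_id = classify_non_medication(text, rules)
        if rule_id is not None:
            excluded[text] = (rule_id, freq)
        else:
            groups.append(GroupedEntry(text, freq))
    groups.sort(key=lambda g: (-g.frequency, g.medication))
    return GroupingResult(groups, excluded, n_input=len(unstructured))


def topN_coverage(
    groups: Sequence[GroupedEntry], n: int, denominator: Optional[int] = None
) -> float:
    """Percentage of unstructured prescriptions covered by the ``n`` most
    frequent free texts.

    ``denominator`` defaults to the groups' own frequency sum; pass the
    pre-exclusion unstructured count to measure coverage against the full
    unstructured corpus (the convention used when deciding how many texts
    to validate manually).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(groups, key=lambda g: (-g.frequency, g.medication))
    covered = sum(g.frequency for g in ordered[:n])
    total = denominator if denominator is not None else sum(g.frequency for g in groups)
    if total == 0:
        return 0.0
    return round_pct(100.0 * covered / total)


# ------------------------------------------------------------------ workbook


def make_workbook(groups: Sequence[GroupedEntry], n: int) -> list[ValidationRecord]:
    """Build DS4 rows for the ``n`` most frequent matched groups: algorithm
    results and concordance flags prefilled, reviewer fields blank."""
    records = []
    for g in groups[:n]:
        top3 = g.step3_top
        flags = concordance(g.step1, g.step2, top3.atc if top3 else None)
        records.append(
            ValidationRecord(
                medication=g.medication,
                frequency=g.frequency,
                step1=g.step1,
                step2=g.step2,
                step3=g.step3,
                true12=flags.true12,
                true13=flags.true13,
                true23=flags.true23,
                true123=flags.true123,
            )
        )
    return records


def export_validation_workbook(
    groups: Sequence[GroupedEntry],
    n: int,
    path,
    config: Optional[DialectConfig] = None,
) -> list[ValidationRecord]:
    """Write the top-``n`` groups as a DS4 workbook for manual review."""
    records = make_workbook(groups, n)
    write_workbook(records, path, config)
    return records


def resolve_final(record: ValidationRecord) -> ValidationRecord:
    """Fill ``final`` for one workbook row.

    Precedence: an explicit reviewer-entered CORRECT code wins; then the
    first algorithm result marked correct (Eval1, Eval2, Eval3 in that
    order); then a label or code the reviewer put in FINAL directly;
    otherwise the row was never evaluated and gets ``no_eval``.
    """
    final: Optional[str] = None
    if record.correct:
        final = record.correct
    elif record.eval1 and record.step1 is not None:
        final = str(record.step1)
    elif record.eval2 and record.step2 is not None:
        final = str(record.step2)
    elif record.eval3 and record.step3_top is not None:
        final = str(record.step3_top.atc)
    elif record.final:
        final = record.final
    record.final = final or "no_eval"
    return record


def import_validation_workbook(path, config: Optional[DialectConfig] = None):
    """Read a (possibly partially filled) DS4 workbook and resolve FINAL
    for every row; returns ``(records, rejected_rows)``."""
    data = read_workbook(path, config)
    return [resolve_final(r) for r in data.records], data.rejects


# ----------------------------------------------------------- final assessment


@dataclass
class FinalAssessment:
    """Final structuredness assessment: overall summary, per-ATC-level-1
    group table and per-ingredient (level-5) table."""

    summary: StructurednessSummary
    group_report: pd.DataFrame
    ingredient_report: pd.DataFrame


def final_assessment(
    structured: Sequence[PrescriptionRecord],
    validation_records: Sequence[ValidationRecord],
    grouping: GroupingResult,
) -> FinalAssessment:
    """Merge structured records with validated free-text resolutions.

    Every prescription lands in exactly one bucket: structured (ATC from
    the source table), validated-unstructured (FINAL ATC code, weighted by
    frequency), non-medication (rule-excluded plus reviewer-flagged
    ``nomed``), ``unspec``, or not validated.  The group report aggregates
    by ATC level 1; level-truncated FINAL codes contribute to their level-1
    group but never to the level-5 ingredient report.
    """
    n_structured = len(structured)
    n_total = n_structured + grouping.n_input

    struct_l1: Counter = Counter()
    struct_l5: Counter = Counter()
    for r in structured:
        struct_l1[str(r.atc_l5.truncate(1))] += 1
        struct_l5[str(r.atc_l5)] += 1

    unstr_l1: Counter = Counter()
    unstr_l5: Counter = Counter()
    n_validated_atc = 0
    n_nomed_wb = 0
    n_unspec = 0
    n_no_eval = 0
    seen_texts: set[str] = set()
    for v in validation_records:
        seen_texts.add(v.medication)
        if v.final == "nomed":
            n_nomed_wb += v.frequency
        elif v.final == "unspec":
            n_unspec += v.frequency
        elif v.final == "no_eval" or v.final is None:
            n_no_eval += v.frequency
        else:
            code = AtcCode(v.final)
            n_validated_atc += v.frequency
            unstr_l1[str(code.truncate(1))] += v.frequency
            if code.level == 5:
                unstr_l5[str(code)] += v.frequency

    n_unvalidated_tail = sum(
        g.frequency for g in grouping.groups if g.medication not in seen_texts
    )
    n_nomed = grouping.n_excluded + n_nomed_wb
    n_not_validated = n_no_eval + n_unvalidated_tail

    summary = StructurednessSummary(
        n_total=n_total,
        n_structured=n_structured,
        n_unstructured=grouping.n_input,
        n_excluded_nomed=n_nomed,
        n_unspec=n_unspec,
        n_validated_unstructured=n_validated_atc,
        n_not_validated=n_not_validated,
    )
    # conservation must hold exactly, on every run
    assert summary.n_validated + summary.n_not_validated == n_total

    classified_total = n_structured + n_validated_atc
    rows = []
    for letter in sorted(set(struct_l1) | set(unstr_l1)):
        s, u = struct_l1[letter], unstr_l1[letter]
        total = s + u
        rows.append(
            {
                "group": letter,
                "structured": s,
                "unstructured": u,
                "total": total,
                "pct_structured": round_pct(100.0 * s / total),
                "pct_unstructured": round_pct(100.0 * u / total),
                "pct_of_total": round_pct(100.0 * total / classified_total)
                if classified_total
                else 0.0,
            }
        )
    rows.sort(key=lambda r: (-r["total"], r["group"]))
    for label, count in (
        ("nomed", n_nomed),
        ("unspec", n_unspec),
        ("not_validated", n_not_validated),
    ):
        rows.append(
            {
                "group": label,
                "structured": 0,
                "unstructured": count,
                "total": count,
                "pct_structured": 0.0,
                "pct_unstructured": 100.0 if count else 0.0,
                "pct_of_total": round_pct(100.0 * count / n_total) if n_total else 0.0,
            }
        )
    group_report = pd.DataFrame(rows)

    ing_rows = []
    for code in sorted(set(struct_l5) | set(unstr_l5)):
        s, u = struct_l5[code], unstr_l5[code]
        total = s + u
        ing_rows.append(
            {
                "atc_l5": code,
                "structured": s,
                "unstructured": u,
                "total": total,
                "pct_structured": round_pct(100.0 * s / total),
            }
        )
    ing_rows.sort(key=lambda r: (-r["total"], r["atc_l5"]))
    ingredient_report = pd.DataFrame(ing_rows)
    return FinalAssessment(summary, group_report, ingredient_report)


# --------------------------------------------------------------- convenience


@dataclass
class PipelineResult:
    initial_summary: StructurednessSummary
    grouping: GroupingResult
    workbook: list
    assessment: FinalAssessment
    coverage_top_n: float


def run_pipeline(
    records: Sequence[PrescriptionRecord],
    catalog: DrugCatalog,
    rules: Sequence[ExclusionRule] = DEFAULT_RULES,
    top_n: int = 1000,
    k: int = 3,
    reviewer: Optional[Callable[[list], list]] = None,
) -> PipelineResult:
    """Run the whole assessment end to end in memory.

    ``reviewer`` fills the Eval/CORRECT/FINAL fields of the workbook rows
    (e.g. a human round trip via the DS4 file, or the fixtures module's
    ground-truth evaluator); with no reviewer every workbook row resolves
    to ``no_eval`` and only partitioning and exclusion move the needle.
    Matching runs on the ``top_n`` most frequent free texts.
    """
    structured, unstructured, initial = partition(records)
    grouping = group_unstructured(unstructured, rules)
    run_cascade(grouping.groups, catalog, k=k, limit=top_n)
    workbook = make_workbook(grouping.groups, top_n)
    if reviewer is not None:
        workbook = reviewer(workbook)
    workbook = [resolve_final(r) for r in workbook]
    assessment = final_assessment(structured, workbook, grouping)
    coverage = topN_coverage(grouping.groups, top_n, denominator=grouping.n_input)
    return PipelineResult(initial, grouping, workbook, assessment, coverage)
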