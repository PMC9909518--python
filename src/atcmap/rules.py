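"""Non-medication exclusion rules and reliability classification.

Free-text prescription fields in hospital systems also carry things that
are not medications at all — laboratory and measurement orders such as
"BGA" (blood gas analysis), "BE" (draw a blood sample) or "BB" (blood
count).  A small configurable rule engine excludes those before matching.

After matching, each entry's reliability is classified from the agreement
pattern of the three algorithms (concordance flags) and, failing that,
from the similarity score of algorithm 3: manual validation shows that
full consensus — or agreement of the two exact algorithms — is essentially
always correct, and that correct similarity matches score markedly higher
than wrong ones (a Welch two-sample t-test quantifies the separation).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .atc import AtcCode, GroupedEntry
from .textnorm import normalize

__all__ = [
    "ExclusionRule",
    "DEFAULT_RULES",
    "load_rules",
    "classify_non_medication",
    "ConcordanceFlags",
    "concordance",
    "Tier",
    "ConfidenceAssignment",
    "assign_confidence",
    "DEFAULT_SCORE_THRESHOLD",
    "GroupStats",
    "ScoreSeparation",
    "score_separation_test",
]

#: Default similarity-score cutoff for the score-based tier: the mean
#: score observed for *correct* similarity matches in validation.  An
#: empirical indication, not a law — always configurable.
DEFAULT_SCORE_THRESHOLD = 84.28


@dataclass(frozen=True)
class ExclusionRule:
    """One non-medication rule: ``prefix`` matches whole leading tokens of
    the normalized text, ``exact`` the whole normalized text, ``regex`` is
    applied to the raw text (case-insensitive)."""

    rule_id: str
    kind: str  # "prefix" | "exact" | "regex"
    pattern: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("prefix", "exact", "regex"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if not self.pattern:
            raise ValueError(f"rule {self.rule_id}: empty pattern")
        if self.kind == "regex":
            re.compile(self.pattern)  # fail fast on bad config

    def matches(self, text: str) -> bool:
        if self.kind == "regex":
            return re.search(self.pattern, text, flags=re.IGNORECASE) is not None
        norm = normalize(text)
        pattern_tokens = normalize(self.pattern).tokens
        if self.kind == "exact":
            return norm.tokens == pattern_tokens
        return bool(pattern_tokens) and norm.tokens[: len(pattern_tokens)] == pattern_tokens


#: The in-text example rules: leading laboratory/measurement order tokens.
DEFAULT_RULES: tuple[ExclusionRule, ...] = (
    ExclusionRule("bga", "prefix", "BGA", "laboratory request for blood gas analysis"),
    ExclusionRule("be", "prefix", "BE", "request to nurses for taking a blood sample"),
    ExclusionRule("bb", "prefix", "BB", "laboratory request for blood count"),
)


def load_rules(path) -> list[ExclusionRule]:
    """Load exclusion rules from a YAML file.

    Schema: a top-level ``rules`` list of mappings with keys ``id``,
    ``kind`` (prefix/exact/regex), ``pattern`` and optional ``description``;
    rules apply in file order, first match wins.
    """
    import yaml

    with open(path, encoding="utf-8") as handle:
        doc = yaml.safe_load(handle) or {}
    entries = doc["rules"] if isinstance(doc, dict) else doc
    return [
        ExclusionRule(
            rule_id=str(item["id"]),
            kind=str(item["kind"]),
            pattern=str(item["pattern"]),
            description=str(item.get("description", "")),
        )
        for item in entries
    ]


def classify_non_medication(text: str, rules: Sequence[ExclusionRule]) -> Optional[str]:
    """Return the id of the first rule matching ``text``, or ``None``."""
    for rule in rules:
        if rule.matches(text):
            return rule.rule_id
    return None


# ------------------------------------------------------------- concordance


@dataclass(frozen=True)
class ConcordanceFlags:
    """Pairwise and three-way agreement of the algorithm results, compared
    at ATC level 5; a missing result makes its pairs false."""

    true12: bool = False
    true13: bool = False
    true23: bool = False
    true123: bool = False

    def __post_init__(self) -> None:
        if self.true123 and not (self.true12 and self.true13 and self.true23):
            raise ValueError("true123 requires all pairwise flags")


def concordance(
    step1: Optional[AtcCode],
    step2: Optional[AtcCode],
    step3_top1: Optional[AtcCode],
) -> ConcordanceFlags:
    """Compute agreement flags for one entry's three algorithm results."""

    def same(x: Optional[AtcCode], y: Optional[AtcCode]) -> bool:
        return x is not None and y is not None and str(x) == str(y)

    t12 = same(step1, step2)
    t13 = same(step1, step3_top1)
    t23 = same(step2, step3_top1)
    return ConcordanceFlags(t12, t13, t23, t12 and t13 and t23)


# ---------------------------------------------------------------- confidence


class Tier(enum.IntEnum):
    """Reliability tiers, totally ordered from least to most trustworthy
    (the excluded tier sits below review because the entry never was a
    medication)."""

    EXCLUDED_NOMED = 0
    NEEDS_REVIEW = 1
    SCORE_BASED = 2
    CONSENSUS_HIGH = 3
    CONSENSUS_EXACT = 4


@dataclass(frozen=True)
class ConfidenceAssignment:
    tier: Tier
    rationale: str


def assign_confidence(
    entry: GroupedEntry,
    flags: ConcordanceFlags,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> ConfidenceAssignment:
    """Classify one (non-excluded) entry's reliability.

    ``consensus_exact``: full consensus or the two exact algorithms agree —
    validated as always correct.  ``consensus_high``: an exact algorithm
    agrees with the similarity match.  ``score_based``: only the similarity
    algorithm answered but its top score exceeds ``score_threshold``
    (strict, matching the ">" framing of the empirical cutoff).  Everything
    else needs manual review.
    """
    if flags.true123 or flags.true12:
        return ConfidenceAssignment(Tier.CONSENSUS_EXACT, "exact algorithms agree")
    if flags.true13 or flags.true23:
        return ConfidenceAssignment(Tier.CONSENSUS_HIGH, "exact and similarity results agree")
    top = entry.step3_top
    if entry.step1 is None and entry.step2 is None and top is not None and top.score is not None:
        if top.score > score_threshold:
            return ConfidenceAssignment(
                Tier.SCORE_BASED, f"similarity-only result with score {top.score} > {score_threshold}"
            )
    return ConfidenceAssignment(Tier.NEEDS_REVIEW, "no agreement and no high similarity score")


# ------------------------------------------------------- score separation


@dataclass(frozen=True)
class GroupStats:
    """Descriptive panel for one score group (sample SD, ddof=1)."""

    count: int
    mean: float
    sd: float
    minimum: float
    q25: float
    median: float
    q75: float
    maximum: float


def _describe(values: np.ndarray) -> GroupStats:
    q25, median, q75 = np.percentile(values, [25, 50, 75])
    return GroupStats(
        count=int(values.size),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        minimum=float(values.min()),
        q25=float(q25),
        median=float(median),
        q75=float(q75),
        maximum=float(values.max()),
    )


@dataclass(frozen=True)
class ScoreSeparation:
    t_statistic: float
    p_value: float
    correct: GroupStats
    wrong: GroupStats


def score_separation_test(
    correct_scores: Sequence[float], wrong_scores: Sequence[float]
) -> ScoreSeparation:
    """Welch's two-sided t-test for mean similarity-score separation
    between validated-correct and validated-wrong similarity matches,
    plus the per-group descriptive panel.

    Welch's unequal-variance form is used because the two groups' spreads
    need not (and empirically do not) match.  Each group needs >= 2 values.
    """
    a = np.asarray(correct_scores, dtype=float)
    b = np.asarray(wrong_scores, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each score group needs at least 2 values")
    t_stat, p_value = stats.ttest_ind(a, b, equal_var=False)
    return ScoreSeparation(float(t_stat), float(p_value), _describe(a), _describe(b))
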