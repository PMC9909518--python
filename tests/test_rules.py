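"""Exclusion rules, concordance flags, confidence tiers and the
score-separation test."""

import itertools
import math

import pytest
from hypothesis import given, strategies as st

from atcmap.atc import AtcCode, GroupedEntry
from atcmap.matchers import MatchCandidate
from atcmap.rules import (
    DEFAULT_RULES,
    ConcordanceFlags,
    ExclusionRule,
    Tier,
    assign_confidence,
    classify_non_medication,
    concordance,
    load_rules,
    score_separation_test,
)

A = AtcCode("M01AE01")
B = AtcCode("N02BE01")


class TestExclusionRules:
    @pytest.mark.parametrize(
        "text, excluded",
        [
            ("BGA", True),
            ("bga kontrolle", True),  # prefix on normalized text
            ("BE 7:30", True),
            ("BB abnehmen", True),
            ("Ibuprofen 600", False),
            ("BEloc 50", False),  # whole-token prefix, not raw substring
            ("Morgen BGA", False),  # leading tokens only
        ],
    )
    def test_default_rules(self, text, excluded):
        assert (classify_non_medication(text, DEFAULT_RULES) is not None) == excluded

    def test_first_matching_rule_wins_in_order(self):
        rules = [
            ExclusionRule("r1", "prefix", "BGA"),
            ExclusionRule("r2", "exact", "BGA"),
        ]
        assert classify_non_medication("BGA", rules) == "r1"

    def test_exact_and_regex_kinds(self):
        rules = [
            ExclusionRule("lab", "exact", "Labor"),
            ExclusionRule("times", "regex", r"^\d{1,2}:\d{2}\b"),
        ]
        assert classify_non_medication("labor", rules) == "lab"
        assert classify_non_medication("Labor anfordern", rules) is None
        assert classify_non_medication("8:30 Blutdruck", rules) == "times"

    def test_empty_rule_list_excludes_nothing(self):
        assert classify_non_medication("BGA", []) is None

    @pytest.mark.parametrize(
        "kind, pattern", [("shout", "BGA"), ("prefix", ""), ("regex", "(")]
    )
    def test_invalid_rules_rejected(self, kind, pattern):
        with pytest.raises(Exception):
            ExclusionRule("bad", kind, pattern)

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "rules.yaml"
        path.write_text(
            "rules:\n"
            "  - {id: bga, kind: prefix, pattern: BGA, description: blood gas}\n"
            "  - {id: ekg, kind: exact, pattern: EKG}\n",
            encoding="utf-8",
        )
        rules = load_rules(path)
        assert [r.rule_id for r in rules] == ["bga", "ekg"]
        assert classify_non_medication("EKG", rules) == "ekg"


class TestConcordance:
    def test_full_agreement(self):
        flags = concordance(A, A, A)
        assert (flags.true12, flags.true13, flags.true23, flags.true123) == (True,) * 4

    def test_missing_result_breaks_its_pairs(self):
        flags = concordance(A, None, A)
        assert flags.true13 and not (flags.true12 or flags.true23 or flags.true123)

    def test_exhaustive_truth_table_matches_brute_force(self):
        # independent oracle: direct enumeration of all 27 combinations
        for s1, s2, s3 in itertools.product((A, B, None), repeat=3):
            flags = concordance(s1, s2, s3)
            expect12 = s1 is not None and s2 is not None and s1 == s2
            expect13 = s1 is not None and s3 is not None and s1 == s3
            expect23 = s2 is not None and s3 is not None and s2 == s3
            assert flags.true12 == expect12
            assert flags.true13 == expect13
            assert flags.true23 == expect23
            assert flags.true123 == (expect12 and expect13 and expect23)
            if flags.true123:
                assert flags.true12 and flags.true13 and flags.true23

    def test_flags_invariant_enforced(self):
        with pytest.raises(ValueError):
            ConcordanceFlags(true12=True, true13=False, true23=False, true123=True)


def entry(step1=None, step2=None, score=None):
    step3 = (MatchCandidate(B, score),) if score is not None else ()
    return GroupedEntry("x", 1, step1=step1, step2=step2, step3=step3)


class TestConfidence:
    def test_exact_consensus(self):
        e = entry(step1=A, step2=A, score=88)
        assert assign_confidence(e, concordance(A, A, B)).tier is Tier.CONSENSUS_EXACT

    def test_high_consensus_via_similarity_agreement(self):
        e = entry(step1=B, score=95)
        assert assign_confidence(e, concordance(B, None, B)).tier is Tier.CONSENSUS_HIGH

    def test_similarity_only_above_threshold(self):
        e = entry(score=90)
        assert assign_confidence(e, concordance(None, None, B)).tier is Tier.SCORE_BASED

    def test_similarity_only_below_threshold(self):
        e = entry(score=60)
        assert assign_confidence(e, concordance(None, None, B)).tier is Tier.NEEDS_REVIEW

    def test_threshold_is_strict(self):
        e = entry(score=84)
        assert assign_confidence(e, concordance(None, None, B), 84).tier is Tier.NEEDS_REVIEW

    def test_disagreement_needs_review(self):
        e = entry(step1=A, score=99)
        assert assign_confidence(e, concordance(A, None, B)).tier is Tier.NEEDS_REVIEW

    @given(st.integers(0, 100), st.integers(0, 100), st.integers(0, 100))
    def test_tier_monotone_in_threshold(self, score, th1, th2):
        th1, th2 = sorted((th1, th2))
        e = entry(score=score)
        flags = concordance(None, None, B)
        low = assign_confidence(e, flags, th1).tier
        high = assign_confidence(e, flags, th2).tier
        assert high <= low  # raising the threshold never promotes an entry


class TestScoreSeparation:
    def test_hand_computed_welch_on_toy_groups(self):
        correct, wrong = [90.0, 95.0, 100.0], [60.0, 70.0, 65.0]
        result = score_separation_test(correct, wrong)
        # closed-form Welch: t = (m1-m2)/sqrt(s1^2/n1 + s2^2/n2)
        m1, m2 = 95.0, 65.0
        v1 = sum((x - m1) ** 2 for x in correct) / 2
        v2 = sum((x - m2) ** 2 for x in wrong) / 2
        t_expected = (m1 - m2) / math.sqrt(v1 / 3 + v2 / 3)
        assert result.t_statistic == pytest.approx(t_expected)
        assert result.correct.mean == pytest.approx(95.0)
        assert result.wrong.sd == pytest.approx(5.0)
        assert result.p_value < 0.01

    def test_identical_groups_do_not_separate(self):
        result = score_separation_test([80.0, 90.0, 85.0], [80.0, 90.0, 85.0])
        assert result.t_statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_descriptive_panel(self):
        result = score_separation_test([21, 76, 87, 96, 100], [29, 55, 63, 75, 100])
        assert result.correct.count == 5
        assert result.correct.minimum == 21 and result.correct.maximum == 100
        assert result.correct.median == 87
        assert result.wrong.q25 == 55 and result.wrong.q75 == 75

    def test_small_group_is_error(self):
        with pytest.raises(ValueError):
            score_separation_test([90.0], [60.0, 70.0])
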