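"""Normalization and the four-similarity-ratio stack, against independent
dynamic-programming oracles and printed worked-example values."""

import random

import pytest
from hypothesis import given, strategies as st

from atcmap.textnorm import (
    indel_distance,
    lcs_length,
    normalize,
    partial_ratio,
    simple_ratio,
    token_set_ratio,
    token_sort_ratio,
)

from conftest import indel_oracle

D1 = "Stada paracetamol"
D2 = "paracetamol Stada 400 mg"

short_text = st.text(alphabet="abcd 0.%|", max_size=25)
tokens = st.lists(st.text(alphabet="abcdef", min_size=1, max_size=6), min_size=1, max_size=6)


class TestNormalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("NaCl 0.9%", ("nacl", "0", "9")),
            ("Stada paracetamol", ("stada", "paracetamol")),
            ("", ()),
            ("ACIC 250 PI Via Pulver z.Herst.e.Infusionslösg.", ("acic", "250", "pi", "via", "pulver", "z", "herst", "e", "infusionslösg")),
            ("a_b(c)|d", ("a", "b", "c", "d")),
        ],
    )
    def test_examples(self, raw, expected):
        assert normalize(raw).tokens == expected

    @given(st.text(max_size=40))
    def test_idempotent_and_clean(self, s):
        norm = normalize(s)
        assert normalize(norm.normalized).normalized == norm.normalized
        assert " ".join(norm.tokens) == norm.normalized
        for tok in norm.tokens:
            assert tok and all(ch.isalnum() for ch in tok)


class TestIndelDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [("abc", "abc", 0), ("abc", "", 3), ("", "", 0), ("abc", "axc", 2)],
    )
    def test_examples(self, a, b, expected):
        assert indel_distance(a, b) == expected

    @given(short_text, short_text)
    def test_matches_dp_oracle(self, a, b):
        assert indel_distance(a, b) == indel_oracle(a, b)

    @given(short_text, short_text)
    def test_symmetry_and_identity(self, a, b):
        assert indel_distance(a, b) == indel_distance(b, a)
        assert (indel_distance(a, b) == 0) == (a == b)

    @given(short_text, short_text, short_text)
    def test_triangle_inequality(self, a, b, c):
        assert indel_distance(a, c) <= indel_distance(a, b) + indel_distance(b, c)

    def test_lcs_on_long_strings_crosses_word_boundary(self):
        # bit-parallel path must stay exact beyond 64 characters
        a = "ab" * 70
        b = "ba" * 70
        assert indel_distance(a, b) == indel_oracle(a, b)


class TestWorkedExample:
    """The printed four-ratio worked example for the lower-cased pair
    'stada paracetamol' vs 'paracetamol stada 400 mg'."""

    def test_simple_ratio(self):
        assert simple_ratio(D1.lower(), D2.lower()) == 54

    def test_partial_ratio(self):
        assert partial_ratio(D1.lower(), D2.lower()) == 65

    def test_token_sort_ratio(self):
        assert token_sort_ratio(D1.lower(), D2.lower()) == 83

    def test_token_set_ratio(self):
        assert token_set_ratio(D1.lower(), D2.lower()) == 100

    def test_case_insensitive_for_token_methods(self):
        assert token_sort_ratio(D1, D2) == 83
        assert token_set_ratio(D1, D2) == 100


class TestRatioProperties:
    @given(short_text, short_text)
    def test_symmetric_bounded_reflexive(self, a, b):
        for ratio in (simple_ratio, partial_ratio, token_sort_ratio, token_set_ratio):
            score = ratio(a, b)
            assert 0 <= score <= 100
            assert score == ratio(b, a)
            assert ratio(a, a) == 100

    @given(short_text, short_text)
    def test_simple_ratio_from_distance(self, a, b):
        total = len(a) + len(b)
        if total == 0:
            assert simple_ratio(a, b) == 100
        else:
            expected = round(100.0 * (total - indel_oracle(a, b)) / total + 1e-9)
            assert simple_ratio(a, b) == expected

    def test_empty_conventions(self):
        assert simple_ratio("", "") == 100
        assert simple_ratio("", "abc") == 0
        assert partial_ratio("", "") == 100
        assert partial_ratio("", "abc") == 0

    def test_rounding_examples(self):
        assert simple_ratio("aaaa", "aaax") == 75  # distance 2 of total 8
        assert simple_ratio("ab", "abx") == 80  # 4/5, exact
        assert simple_ratio("abcdefg", "abcdefgx") == 93  # 14/15 = 93.33 rounds down
        assert simple_ratio("abc", "abcx") == 86  # 6/7 = 85.71 rounds up


class TestPartialRatio:
    def test_substring_scores_100(self):
        assert partial_ratio("paracetamol", "ibuprofen paracetamol 600") == 100

    @given(short_text.filter(bool), short_text, short_text)
    def test_substring_property(self, s, prefix, suffix):
        assert partial_ratio(s, prefix + s + suffix) == 100

    @given(short_text, short_text)
    def test_at_least_simple_ratio_on_equal_lengths(self, a, b):
        if len(a) == len(b):
            assert partial_ratio(a, b) == simple_ratio(a, b)


class TestTokenMethods:
    def test_sort_rule_reduces_to_simple_ratio(self):
        assert token_sort_ratio("a b", "b a c") == simple_ratio("a b", "a b c")

    @given(tokens)
    def test_permutation_scores_100(self, toks):
        rng = random.Random(42)
        shuffled = toks[:]
        rng.shuffle(shuffled)
        assert token_sort_ratio(" ".join(toks), " ".join(shuffled)) == 100

    @given(tokens, tokens)
    def test_subset_scores_100(self, ta, tb):
        a = " ".join(ta)
        b = " ".join(ta + tb)  # tokens(a) is a subset of tokens(b)
        assert token_set_ratio(a, b) == 100

    def test_disjoint_sets_fall_back_to_remainder_ratio(self):
        # no shared tokens and no shared characters: t0 empty
        assert token_set_ratio("aaa", "zzz") == simple_ratio("aaa", "zzz")

    @given(short_text, short_text)
    def test_token_set_dominates_token_sort_without_duplicates(self, a, b):
        # The set construction can only remove penalty — as long as no
        # information is lost when duplicate tokens collapse to one.
        ta, tb = normalize(a).tokens, normalize(b).tokens
        if len(set(ta)) == len(ta) and len(set(tb)) == len(tb):
            assert token_set_ratio(a, b) >= token_sort_ratio(a, b)

    def test_duplicate_collapse_can_undercut_token_sort(self):
        # "0.0" tokenizes to two copies of "0", which the set construction
        # collapses; DP oracle values: token_set max(0, 0, ratio("00","0"))
        # = 67 while token_sort compares "00" with "0 0" = 80.
        assert indel_oracle("00", "0") == 1 and indel_oracle("00", "0 0") == 1
        assert token_set_ratio("00", "0.0") == 67
        assert token_sort_ratio("00", "0.0") == 80
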