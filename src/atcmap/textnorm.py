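"""Text normalization and the similarity-ratio stack used for drug-name matching.

All scores are integers in [0, 100] built on the *indel* edit distance
(insertions and deletions only, substitutions counted as two operations),
which satisfies ``indel(a, b) = |a| + |b| - 2 * LCS(a, b)``.  The four
ratios — simple, partial, token-sort and token-set — mirror the classic
FuzzyWuzzy stack used for approximate drug-name matching: the token-set
ratio scores 100 whenever every token of one string occurs in the other,
which is exactly the behaviour wanted when a free-text prescription is a
subset of a catalog product name ("paracetamol" vs "PARACETAMOL STADA
500 mg Tabletten").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from difflib import SequenceMatcher
from typing import Iterable

__all__ = [
    "TokenizedText",
    "normalize",
    "lcs_length",
    "indel_distance",
    "simple_ratio",
    "partial_ratio",
    "token_sort_ratio",
    "token_set_ratio",
]


@dataclass(frozen=True)
class TokenizedText:
    """A string together with its normalized form and token list.

    ``normalized`` is the original lower-cased with every character that is
    not a Unicode letter or digit replaced by a space, runs of whitespace
    collapsed and the ends trimmed; ``tokens`` are the whitespace tokens of
    that form.  Normalization is idempotent.
    """

    original: str
    normalized: str
    tokens: tuple[str, ...]


def normalize(s: str) -> TokenizedText:
    """Lower-case, map punctuation to spaces, collapse whitespace, tokenize.

    Any character that is not a Unicode letter or digit counts as
    punctuation (so ``.``, ``%``, ``|``, ``(``, ``)`` and underscore all
    split tokens): ``"NaCl 0.9%"`` tokenizes to ``["nacl", "0", "9"]``.
    """
    cleaned = "".join(ch.lower() if ch.isalnum() else " " for ch in s)
    tokens = tuple(cleaned.split())
    return TokenizedText(original=s, normalized=" ".join(tokens), tokens=tokens)


def lcs_length(a: str, b: str) -> int:
    """Length of the longest common subsequence of ``a`` and ``b``.

    Bit-parallel formulation: one machine word column per 64 characters of
    ``a``, O(|a|/w * |b|) time, exact for arbitrary Unicode strings.
    """
    if not a or not b:
        return 0
    masks: dict[str, int] = {}
    for i, ch in enumerate(a):
        masks[ch] = masks.get(ch, 0) | (1 << i)
    width = (1 << len(a)) - 1
    v = width
    for ch in b:
        u = v & masks.get(ch, 0)
        v = ((v + u) | (v - u)) & width
    return bin(~v & width).count("1")


def indel_distance(a: str, b: str) -> int:
    """Edit distance allowing insertions and deletions only.

    Equals ``|a| + |b| - 2 * LCS(a, b)``; symmetric, zero iff the strings
    are equal, and a substitution costs 2 (one deletion plus one
    insertion).
    """
    return len(a) + len(b) - 2 * lcs_length(a, b)


def _round_half_away(x: float) -> int:
    # scores are non-negative; round-half-up == round half away from zero
    return int(math.floor(x + 0.5))


def simple_ratio(a: str, b: str) -> int:
    """Normalized indel similarity of two raw strings, 0–100.

    ``round(100 * (|a| + |b| - indel) / (|a| + |b|))`` with half-away-from-
    zero rounding; two empty strings score 100 (and one empty string scores
    0, since the distance then equals the total length).
    """
    total = len(a) + len(b)
    if total == 0:
        return 100
    return _round_half_away(100.0 * (total - indel_distance(a, b)) / total)


def partial_ratio(a: str, b: str) -> int:
    """Best ``simple_ratio`` of the shorter string against same-length
    windows of the longer one.

    Candidate windows are anchored at the start positions implied by the
    longest-matching-block alignments between the two strings (clamped to
    the valid range); ties are broken by the leftmost window.  A verbatim
    substring therefore scores 100.
    """
    if len(a) <= len(b):
        shorter, longer = a, b
    else:
        shorter, longer = b, a
    if not shorter:
        return 100 if not longer else 0
    if len(shorter) == len(longer):
        return simple_ratio(shorter, longer)
    matcher = SequenceMatcher(None, shorter, longer, autojunk=False)
    best = 0
    seen: set[int] = set()
    for i, j, _size in matcher.get_matching_blocks():
        start = min(max(j - i, 0), len(longer) - len(shorter))
        if start in seen:
            continue
        seen.add(start)
        window = longer[start : start + len(shorter)]
        score = simple_ratio(shorter, window)
        if score > best:
            best = score
            if best == 100:
                break
    return min(best, 100)


def _sorted_join(tokens: Iterable[str]) -> str:
    return " ".join(sorted(tokens))


def token_sort_ratio(a: str, b: str) -> int:
    """``simple_ratio`` of the two strings rebuilt as alphabetically sorted
    normalized tokens joined by single spaces."""
    return simple_ratio(_sorted_join(normalize(a).tokens), _sorted_join(normalize(b).tokens))


def token_set_ratio(a: str, b: str) -> int:
    """Similarity that ignores word order and tolerates extra words.

    Tokens of each normalized string are split into the intersection group
    and the two remainder groups; with ``t0`` the sorted intersection,
    ``t1 = t0 + remainder(a)`` and ``t2 = t0 + remainder(b)`` (sorted,
    space-joined, trimmed), the score is
    ``max(simple_ratio(t0, t1), simple_ratio(t0, t2), simple_ratio(t1, t2))``.
    Whenever one token set is contained in the other the score is 100.
    """
    return _token_set_ratio_tokens(frozenset(normalize(a).tokens), frozenset(normalize(b).tokens))


def _token_set_ratio_tokens(set_a: frozenset[str], set_b: frozenset[str]) -> int:
    """Token-set ratio on pre-normalized token sets (hot path for matching
    one query against a whole catalog)."""
    if set_a <= set_b or set_b <= set_a:
        return 100  # t0 equals t1 or t2 exactly
    inter = sorted(set_a & set_b)
    t0 = " ".join(inter)
    t1 = " ".join(inter + sorted(set_a - set_b)).strip()
    t2 = " ".join(inter + sorted(set_b - set_a)).strip()
    return max(simple_ratio(t0, t1), simple_ratio(t0, t2), simple_ratio(t1, t2))
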