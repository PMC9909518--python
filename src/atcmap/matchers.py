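"""The three ATC-identification algorithms run against a drug catalog.

Algorithm 1 looks for a catalog *ingredient* name inside the free text,
algorithm 2 for a *product* name, both as whole-token phrase containment
after normalization (raw substring search would fire inside longer words —
"ASS" inside "WASSER" — and destroy the near-perfect precision these
algorithms are valued for).  Algorithm 3 scores the text against every
ingredient and product name with the token-set ratio and returns the top-k
candidate ATC codes with their scores; by construction it answers for
every non-degenerate query.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .atc import AtcCode, DrugCatalog, GroupedEntry
from .textnorm import _token_set_ratio_tokens, normalize

__all__ = [
    "MatchCandidate",
    "MatchResult",
    "match_by_ingredient",
    "match_by_product",
    "match_by_similarity",
    "run_cascade",
]


@dataclass(frozen=True)
class MatchCandidate:
    """One candidate ATC code with the catalog name that produced it.

    Exact (algorithm 1/2) matches carry score 100; ``source`` records which
    name column matched and is ``None`` for candidates deserialized from a
    DS3/DS4 file, where only code and score are stored.
    """

    atc: AtcCode
    score: Optional[int]
    matched_name: str = ""
    source: Optional[str] = None  # "ingredient" | "product"


@dataclass(frozen=True)
class MatchResult:
    """Result of one algorithm: an ordered candidate list (at most one for
    algorithms 1/2, at most k for algorithm 3), scores non-increasing."""

    algorithm: str  # "alg1" | "alg2" | "alg3"
    candidates: tuple[MatchCandidate, ...] = ()

    @property
    def top(self) -> Optional[MatchCandidate]:
        return self.candidates[0] if self.candidates else None

    @property
    def atc(self) -> Optional[AtcCode]:
        return self.candidates[0].atc if self.candidates else None

    def __bool__(self) -> bool:
        return bool(self.candidates)


def _contains_phrase(text_tokens: Sequence[str], phrase: Sequence[str]) -> bool:
    """Whole-token contiguous containment of ``phrase`` in ``text_tokens``."""
    n, m = len(text_tokens), len(phrase)
    if m == 0 or m > n:
        return False
    first = phrase[0]
    for i in range(n - m + 1):
        if text_tokens[i] == first and list(text_tokens[i : i + m]) == list(phrase):
            return True
    return False


def _match_by_name(text: str, catalog: DrugCatalog, source: str, algorithm: str) -> MatchResult:
    text_tokens = normalize(text).tokens
    if not text_tokens:
        return MatchResult(algorithm)
    hits = [
        (toks, name, atc)
        for toks, _tokset, name, atc in catalog.indexed_names(source)
        if _contains_phrase(text_tokens, toks)
    ]
    if not hits:
        return MatchResult(algorithm)
    # longest matching name wins: most tokens, then most characters
    best_len = max((len(toks), len(name)) for toks, name, _ in hits)
    survivors = [(name, atc) for toks, name, atc in hits if (len(toks), len(name)) == best_len]
    atcs = {atc for _, atc in survivors}
    if len(atcs) != 1:
        return MatchResult(algorithm)  # ambiguous -> precision-first: no result
    name, atc = sorted(survivors)[0]
    return MatchResult(algorithm, (MatchCandidate(atc, 100, name, source),))


def match_by_ingredient(text: str, catalog: DrugCatalog) -> MatchResult:
    """Algorithm 1: recognize a catalog ingredient name within the text.

    The longest ingredient name whose tokens occur contiguously in the
    normalized text wins; if equally long matches map to more than one
    distinct ATC code the result is empty (ambiguous)."""
    return _match_by_name(text, catalog, "ingredient", "alg1")


def match_by_product(text: str, catalog: DrugCatalog) -> MatchResult:
    """Algorithm 2: recognize a catalog product name within the text."""
    return _match_by_name(text, catalog, "product", "alg2")


def match_by_similarity(text: str, catalog: DrugCatalog, k: int = 3) -> MatchResult:
    """Algorithm 3: token-set-ratio similarity against every catalog
    ingredient and product name.

    Candidates are deduplicated by ATC code keeping each code's best score,
    ranked by score descending with deterministic tie-breaks (longer
    matched name first, then lexicographic ATC), and the top ``k``
    returned.  Empty catalog is an error; a query with no tokens after
    normalization yields an empty result (every score would degenerate)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(catalog) == 0:
        raise ValueError("cannot run similarity matching against an empty catalog")
    text_set = frozenset(normalize(text).tokens)
    if not text_set:
        return MatchResult("alg3")
    best: dict[AtcCode, MatchCandidate] = {}
    for source in ("ingredient", "product"):
        for _toks, tokset, name, atc in catalog.indexed_names(source):
            score = _token_set_ratio_tokens(text_set, tokset)
            cur = best.get(atc)
            if cur is None or (score, len(name)) > (cur.score, len(cur.matched_name)):
                best[atc] = MatchCandidate(atc, score, name, source)
    ranked = sorted(
        best.values(), key=lambda c: (-c.score, -len(c.matched_name), str(c.atc))
    )
    return MatchResult("alg3", tuple(ranked[:k]))


def run_cascade(
    groups: Sequence[GroupedEntry],
    catalog: DrugCatalog,
    k: int = 3,
    limit: Optional[int] = None,
) -> list[GroupedEntry]:
    """Run all three algorithms over grouped free texts, filling the
    ``step1``/``step2``/``step3`` fields in place.

    ``limit`` restricts the (quadratic-cost) similarity matching and the
    exact matchers to the first ``limit`` groups — in practice the
    most-frequent texts, since grouped data arrives frequency-sorted.
    Returns the same list for convenience.
    """
    todo = groups if limit is None else groups[:limit]
    for g in todo:
        g.step1 = match_by_ingredient(g.medication, catalog).atc
        g.step2 = match_by_product(g.medication, catalog).atc
        g.step3 = match_by_similarity(g.medication, catalog, k).candidates
    return list(groups)
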