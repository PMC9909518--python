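"""ATC code semantics and the in-memory data model.

The WHO ATC (Anatomical Therapeutic Chemical) classification is a 5-level
hierarchy: level 1 is one of 14 anatomical main groups (a single letter),
level 2 a therapeutic subgroup (letter + two digits), levels 3 and 4 add
one letter each, and level 5 — the chemical substance / ingredient — is the
full 7-character code (e.g. ``N02BB02``, metamizole).  Codes at any level
are string prefixes of their level-5 descendants, so grouping by level 1
is plain prefix truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

__all__ = [
    "LEVEL1_GROUPS",
    "AtcValidationError",
    "AtcCode",
    "parse_atc",
    "truncate_atc",
    "CatalogEntry",
    "DrugCatalog",
    "PrescriptionRecord",
    "GroupedEntry",
    "ValidationRecord",
    "RejectedRow",
]

#: The 14 anatomical main-group letters of ATC level 1.
LEVEL1_GROUPS = frozenset("ABCDGHJLMNPRSV")

_LENGTH_TO_LEVEL = {1: 1, 3: 2, 4: 3, 5: 4, 7: 5}
_LEVEL_TO_LENGTH = {lvl: length for length, lvl in _LENGTH_TO_LEVEL.items()}

#: Final-assessment labels that may stand in for an ATC code.
LABELS = ("nomed", "unspec", "no_eval")


class AtcValidationError(ValueError):
    """Raised when a string is not a well-formed ATC code."""


class AtcCode(str):
    """A validated ATC code at any of the 5 hierarchy levels.

    Subclasses :class:`str`, so it compares and hashes like its text and
    serializes transparently; construction upper-cases the input and
    validates length and per-position character classes.
    """

    __slots__ = ()

    def __new__(cls, code: str) -> "AtcCode":
        text = str(code).strip().upper()
        if len(text) not in _LENGTH_TO_LEVEL:
            raise AtcValidationError(
                f"invalid ATC code {code!r}: length {len(text)} not in "
                f"{sorted(_LENGTH_TO_LEVEL)} (levels 1-5)"
            )
        for pos, ch in enumerate(text, start=1):
            if pos == 1:
                if ch not in LEVEL1_GROUPS:
                    raise AtcValidationError(
                        f"invalid ATC code {code!r}: position 1 ({ch!r}) is not "
                        f"one of the 14 level-1 group letters"
                    )
            elif pos in (2, 3, 6, 7):
                if not ch.isdigit():
                    raise AtcValidationError(
                        f"invalid ATC code {code!r}: position {pos} ({ch!r}) must be a digit"
                    )
            else:  # positions 4, 5
                if not ("A" <= ch <= "Z"):
                    raise AtcValidationError(
                        f"invalid ATC code {code!r}: position {pos} ({ch!r}) must be a letter"
                    )
        return str.__new__(cls, text)

    @property
    def level(self) -> int:
        return _LENGTH_TO_LEVEL[len(self)]

    def truncate(self, level: int) -> "AtcCode":
        """Prefix of this code at the given (coarser or equal) level."""
        if not 1 <= level <= self.level:
            raise AtcValidationError(
                f"cannot truncate level-{self.level} code {self!s} to level {level}"
            )
        return AtcCode(str(self)[: _LEVEL_TO_LENGTH[level]])


def parse_atc(code: str) -> AtcCode:
    """Parse and validate an ATC code string (case-insensitive)."""
    return AtcCode(code)


def truncate_atc(code: "AtcCode | str", level: int) -> AtcCode:
    """Truncate an ATC code to a coarser hierarchy level (1 is identity
    for level-1 codes; truncating to the code's own level returns it)."""
    if not isinstance(code, AtcCode):
        code = AtcCode(code)
    return code.truncate(level)


@dataclass(frozen=True)
class CatalogEntry:
    """One drug-product row of the catalog: product name, ingredient name
    (may be empty, e.g. for multi-component infusions listed without one)
    and the product's ATC level-5 code."""

    product_name: str
    ingredient_name: str
    atc_code: AtcCode
    legacy: bool = False

    def __post_init__(self) -> None:
        if not self.product_name:
            raise ValueError("catalog entry needs a non-empty product name")
        if self.atc_code.level != 5:
            raise ValueError(f"catalog ATC code must be level 5, got {self.atc_code!s}")


@dataclass(frozen=True)
class RejectedRow:
    """A quarantined input row with the reason it was rejected."""

    row_number: int
    data: dict
    reason: str


class DrugCatalog:
    """Indexed collection of catalog entries.

    Exact duplicate rows are dropped at construction (count kept in
    :attr:`n_duplicates_dropped`); rows rejected by the reader travel in
    :attr:`rejects` so nothing is silently lost.
    """

    def __init__(
        self,
        entries: Sequence[CatalogEntry],
        rejects: Sequence[RejectedRow] = (),
        encoding: str = "utf-8",
    ) -> None:
        seen: set[tuple[str, str, str, bool]] = set()
        deduped: list[CatalogEntry] = []
        for e in entries:
            key = (e.product_name, e.ingredient_name, str(e.atc_code), e.legacy)
            if key in seen:
                continue
            seen.add(key)
            deduped.append(e)
        self.entries: list[CatalogEntry] = deduped
        self.n_duplicates_dropped: int = len(entries) - len(deduped)
        self.rejects: list[RejectedRow] = list(rejects)
        self.encoding = encoding
        self._name_cache: dict[str, list] = {}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[CatalogEntry]:
        return iter(self.entries)

    def without_legacy(self) -> "DrugCatalog":
        """Copy of the catalog with legacy products filtered out."""
        return DrugCatalog([e for e in self.entries if not e.legacy], self.rejects, self.encoding)

    def indexed_names(self, source: str) -> list:
        """Pre-normalized name index for the matchers.

        ``source`` is ``"ingredient"`` or ``"product"``; returns a list of
        ``(tokens, token_set, raw_name, atc)`` with empty names skipped.
        Cached per catalog instance.
        """
        if source not in ("ingredient", "product"):
            raise ValueError(f"unknown name source {source!r}")
        if source not in self._name_cache:
            from .textnorm import normalize  # local import avoids cycle at import time

            index = []
            seen: set[tuple[str, str]] = set()
            for e in self.entries:
                name = e.ingredient_name if source == "ingredient" else e.product_name
                if not name:
                    continue
                key = (name, str(e.atc_code))
                if key in seen:
                    continue
                seen.add(key)
                toks = normalize(name).tokens
                if toks:
                    index.append((toks, frozenset(toks), name, e.atc_code))
            self._name_cache[source] = index
        return self._name_cache[source]


@dataclass(frozen=True)
class PrescriptionRecord:
    """One prescription row: the MEDICATION text, its year, whether it was
    picked from the catalog (structured) and, if so, its ATC level-5 code.

    Invariant: ``structured`` implies ``atc_l5`` is present and level 5;
    unstructured records carry no code.
    """

    medication: str
    year: int
    structured: bool
    atc_l5: Optional[AtcCode] = None

    def __post_init__(self) -> None:
        if self.structured:
            if self.atc_l5 is None or self.atc_l5.level != 5:
                raise ValueError(
                    f"structured record {self.medication!r} requires an ATC level-5 code"
                )
        elif self.atc_l5 is not None:
            raise ValueError(
                f"unstructured record {self.medication!r} must not carry an ATC code"
            )


@dataclass
class GroupedEntry:
    """A unique free-text MEDICATION with its frequency and the per-
    algorithm results (the grouped data set the cascade operates on)."""

    medication: str
    frequency: int
    step1: Optional[AtcCode] = None
    step2: Optional[AtcCode] = None
    step3: tuple = ()  # ranked tuple of matchers.MatchCandidate

    def __post_init__(self) -> None:
        if self.frequency < 1:
            raise ValueError("frequency must be a positive integer")

    @property
    def step3_top(self):
        return self.step3[0] if self.step3 else None


@dataclass
class ValidationRecord:
    """One row of the validation workbook after import: algorithm results,
    reviewer evaluations, concordance flags and the finally determined ATC
    code (or one of the labels ``nomed`` / ``unspec`` / ``no_eval``)."""

    medication: str
    frequency: int
    step1: Optional[AtcCode] = None
    step2: Optional[AtcCode] = None
    step3: tuple = ()
    eval1: Optional[bool] = None
    eval2: Optional[bool] = None
    eval3: Optional[bool] = None
    true12: bool = False
    true13: bool = False
    true23: bool = False
    true123: bool = False
    correct: Optional[str] = None  # reviewer-entered ATC, may be level 3/4
    comments: str = ""
    final: Optional[str] = None  # ATC code (level >= 3) or a label

    @property
    def step3_top(self):
        return self.step3[0] if self.step3 else None

    @property
    def final_is_label(self) -> bool:
        return self.final in LABELS
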