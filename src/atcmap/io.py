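"""Delimited-text I/O for the four data-set schemas.

DS1 is the raw prescription table (``MEDICATION, YEAR, STRUCTURE,
ATC_L5``), DS2 the drug product catalog (``Product_name, Ingredient_name,
Atc_code``), DS3 the grouped unique free texts with per-algorithm results
(``MEDICATION, FREQUENCY, Step1..Step3``) and DS4 the validation workbook
(DS3 plus ``Eval1..3, True12..True123, CORRECT, COMMENTS, FINAL``).

Readers never silently drop data: rows that fail validation are
quarantined into a rejects list carrying the row number and reason, and
``accepted + rejected == input`` holds for every file.  Files are read as
UTF-8 with a Latin-1 fallback (German product names carry umlauts and ß,
and hospital exports are not always consistently encoded); the encoding
actually used is logged and recorded on the result.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .atc import (
    AtcCode,
    AtcValidationError,
    CatalogEntry,
    DrugCatalog,
    GroupedEntry,
    PrescriptionRecord,
    RejectedRow,
    ValidationRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DialectConfig",
    "SchemaError",
    "DS1_COLUMNS",
    "DS2_COLUMNS",
    "DS3_COLUMNS",
    "DS4_COLUMNS",
    "read_catalog",
    "write_catalog",
    "read_prescriptions",
    "write_prescriptions",
    "read_grouped",
    "write_grouped",
    "read_workbook",
    "write_workbook",
    "write_rejects",
]

DS1_COLUMNS = ("MEDICATION", "YEAR", "STRUCTURE", "ATC_L5")
DS2_COLUMNS = ("Product_name", "Ingredient_name", "Atc_code")
DS3_COLUMNS = ("MEDICATION", "FREQUENCY", "Step1", "Step2", "Step3")
DS4_COLUMNS = DS3_COLUMNS + (
    "Eval1",
    "Eval2",
    "Eval3",
    "True12",
    "True13",
    "True23",
    "True123",
    "CORRECT",
    "COMMENTS",
    "FINAL",
)

_TRUE = {"true", "t", "1", "yes", "wahr"}
_FALSE = {"false", "f", "0", "no", "falsch"}


class SchemaError(ValueError):
    """A required column is missing or the file dialect is unusable."""


@dataclass(frozen=True)
class DialectConfig:
    """How to read/write a delimited file: separator and header overrides.

    ``columns`` maps the default header name (as in the schemas above) to
    the name actually used in the file, e.g. ``{"MEDICATION": "med_text"}``.
    """

    sep: str = ","
    columns: dict = field(default_factory=dict)

    def name(self, default: str) -> str:
        return self.columns.get(default, default)


def _read_table(path, config: DialectConfig) -> tuple[pd.DataFrame, str]:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=config.sep, dtype=str, keep_default_na=False, encoding="utf-8")
        encoding = "utf-8"
    except UnicodeDecodeError:
        frame = pd.read_csv(path, sep=config.sep, dtype=str, keep_default_na=False, encoding="latin-1")
        encoding = "latin-1"
        logger.warning("%s: not valid UTF-8, fell back to Latin-1", path)
    logger.debug("%s: read %d rows as %s", path, len(frame), encoding)
    return frame, encoding


def _require(frame: pd.DataFrame, config: DialectConfig, defaults: Sequence[str], path) -> None:
    missing = [config.name(c) for c in defaults if config.name(c) not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; found {list(frame.columns)}")


def _parse_bool(raw: str) -> Optional[bool]:
    text = raw.strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    return None


# ---------------------------------------------------------------- DS2 catalog


def read_catalog(
    path,
    config: Optional[DialectConfig] = None,
    legacy_column: Optional[str] = None,
) -> DrugCatalog:
    """Read a DS2 drug product catalog.

    Rows with malformed ATC codes or empty product names are quarantined in
    ``catalog.rejects``; exact duplicates are dropped with a logged count.
    ``legacy_column``, when given, names a boolean column flagging legacy
    products (kept in the catalog; filter with
    :meth:`~atcmap.atc.DrugCatalog.without_legacy`).
    """
    config = config or DialectConfig()
    frame, encoding = _read_table(path, config)
    _require(frame, config, DS2_COLUMNS, path)
    entries: list[CatalogEntry] = []
    rejects: list[RejectedRow] = []
    for row_number, row in enumerate(frame.to_dict("records"), start=2):  # 1 = header line
        product = row[config.name("Product_name")].strip()
        ingredient = row[config.name("Ingredient_name")].strip()
        raw_atc = row[config.name("Atc_code")].strip()
        legacy = bool(_parse_bool(row.get(legacy_column, ""))) if legacy_column else False
        try:
            atc = AtcCode(raw_atc)
            if atc.level != 5:
                raise AtcValidationError(f"catalog ATC code must be level 5, got {atc!s}")
            entries.append(CatalogEntry(product, ingredient, atc, legacy))
        except (AtcValidationError, ValueError) as exc:
            rejects.append(RejectedRow(row_number, row, str(exc)))
    catalog = DrugCatalog(entries, rejects, encoding)
    if catalog.n_duplicates_dropped:
        logger.info("%s: dropped %d exact duplicate catalog rows", path, catalog.n_duplicates_dropped)
    return catalog


def write_catalog(catalog: DrugCatalog, path, config: Optional[DialectConfig] = None) -> None:
    config = config or DialectConfig()
    frame = pd.DataFrame(
        {
            config.name("Product_name"): [e.product_name for e in catalog],
            config.name("Ingredient_name"): [e.ingredient_name for e in catalog],
            config.name("Atc_code"): [str(e.atc_code) for e in catalog],
        }
    )
    frame.to_csv(path, sep=config.sep, index=False, quoting=csv.QUOTE_MINIMAL)


# ----------------------------------------------------------- DS1 prescriptions


@dataclass
class PrescriptionData:
    """Result of reading a DS1 file: accepted records plus quarantined rows."""

    records: list
    rejects: list
    encoding: str = "utf-8"


def read_prescriptions(path, config: Optional[DialectConfig] = None) -> PrescriptionData:
    """Read a DS1 prescription table.

    Rows violating the structured⇒ATC invariant (``STRUCTURE`` true without
    a valid level-5 code, or false with one), or with unparseable
    ``YEAR``/``STRUCTURE`` fields, are quarantined with reasons.
    """
    config = config or DialectConfig()
    frame, encoding = _read_table(path, config)
    _require(frame, config, DS1_COLUMNS, path)
    records: list[PrescriptionRecord] = []
    rejects: list[RejectedRow] = []
    for row_number, row in enumerate(frame.to_dict("records"), start=2):
        medication = row[config.name("MEDICATION")]
        raw_year = row[config.name("YEAR")].strip()
        raw_structure = row[config.name("STRUCTURE")].strip()
        raw_atc = row[config.name("ATC_L5")].strip()
        try:
            structured = _parse_bool(raw_structure)
            if structured is None:
                raise ValueError(f"STRUCTURE {raw_structure!r} is not a boolean")
            year = int(raw_year) if raw_year else 0
            atc = AtcCode(raw_atc) if raw_atc else None
            records.append(PrescriptionRecord(medication, year, structured, atc))
        except (AtcValidationError, ValueError) as exc:
            rejects.append(RejectedRow(row_number, row, str(exc)))
    return PrescriptionData(records, rejects, encoding)


def write_prescriptions(records: Sequence[PrescriptionRecord], path, config: Optional[DialectConfig] = None) -> None:
    config = config or DialectConfig()
    frame = pd.DataFrame(
        {
            config.name("MEDICATION"): [r.medication for r in records],
            config.name("YEAR"): [r.year for r in records],
            config.name("STRUCTURE"): ["TRUE" if r.structured else "FALSE" for r in records],
            config.name("ATC_L5"): [str(r.atc_l5) if r.atc_l5 else "" for r in records],
        }
    )
    frame.to_csv(path, sep=config.sep, index=False, quoting=csv.QUOTE_MINIMAL)


# ------------------------------------------------------------------ DS3 / DS4


def _format_step3(candidates) -> str:
    return ";".join(
        f"{c.atc}:{c.score}" if c.score is not None else str(c.atc) for c in candidates
    )


def _parse_step3(raw: str):
    from .matchers import MatchCandidate  # deferred: io <-> matchers layering

    candidates = []
    for part in raw.split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" in part:
            code, score = part.rsplit(":", 1)
            candidates.append(MatchCandidate(AtcCode(code), int(score), "", None))
        else:
            candidates.append(MatchCandidate(AtcCode(part), None, "", None))
    return tuple(candidates)


def _parse_opt_atc(raw: str) -> Optional[AtcCode]:
    raw = raw.strip()
    return AtcCode(raw) if raw else None


def write_grouped(groups: Sequence[GroupedEntry], path, config: Optional[DialectConfig] = None) -> None:
    config = config or DialectConfig()
    frame = pd.DataFrame(
        {
            config.name("MEDICATION"): [g.medication for g in groups],
            config.name("FREQUENCY"): [g.frequency for g in groups],
            config.name("Step1"): [str(g.step1) if g.step1 else "" for g in groups],
            config.name("Step2"): [str(g.step2) if g.step2 else "" for g in groups],
            config.name("Step3"): [_format_step3(g.step3) for g in groups],
        }
    )
    frame.to_csv(path, sep=config.sep, index=False, quoting=csv.QUOTE_MINIMAL)


@dataclass
class GroupedData:
    groups: list
    rejects: list
    encoding: str = "utf-8"


def read_grouped(path, config: Optional[DialectConfig] = None) -> GroupedData:
    """Read a DS3 file; Step3 accepts ``ATC:score;ATC:score`` rank lists."""
    config = config or DialectConfig()
    frame, encoding = _read_table(path, config)
    _require(frame, config, DS3_COLUMNS, path)
    groups: list[GroupedEntry] = []
    rejects: list[RejectedRow] = []
    for row_number, row in enumerate(frame.to_dict("records"), start=2):
        try:
            groups.append(
                GroupedEntry(
                    medication=row[config.name("MEDICATION")],
                    frequency=int(row[config.name("FREQUENCY")]),
                    step1=_parse_opt_atc(row[config.name("Step1")]),
                    step2=_parse_opt_atc(row[config.name("Step2")]),
                    step3=_parse_step3(row[config.name("Step3")]),
                )
            )
        except (AtcValidationError, ValueError) as exc:
            rejects.append(RejectedRow(row_number, row, str(exc)))
    return GroupedData(groups, rejects, encoding)


def _format_opt_bool(value: Optional[bool]) -> str:
    if value is None:
        return ""
    return "TRUE" if value else "FALSE"


def write_workbook(records: Sequence[ValidationRecord], path, config: Optional[DialectConfig] = None) -> None:
    """Write a DS4 validation workbook as delimited text."""
    config = config or DialectConfig()
    columns: dict[str, list] = {config.name(c): [] for c in DS4_COLUMNS}
    for r in records:
        columns[config.name("MEDICATION")].append(r.medication)
        columns[config.name("FREQUENCY")].append(r.frequency)
        columns[config.name("Step1")].append(str(r.step1) if r.step1 else "")
        columns[config.name("Step2")].append(str(r.step2) if r.step2 else "")
        columns[config.name("Step3")].append(_format_step3(r.step3))
        columns[config.name("Eval1")].append(_format_opt_bool(r.eval1))
        columns[config.name("Eval2")].append(_format_opt_bool(r.eval2))
        columns[config.name("Eval3")].append(_format_opt_bool(r.eval3))
        columns[config.name("True12")].append("TRUE" if r.true12 else "FALSE")
        columns[config.name("True13")].append("TRUE" if r.true13 else "FALSE")
        columns[config.name("True23")].append("TRUE" if r.true23 else "FALSE")
        columns[config.name("True123")].append("TRUE" if r.true123 else "FALSE")
        columns[config.name("CORRECT")].append(r.correct or "")
        columns[config.name("COMMENTS")].append(r.comments)
        columns[config.name("FINAL")].append(r.final or "")
    pd.DataFrame(columns).to_csv(path, sep=config.sep, index=False, quoting=csv.QUOTE_MINIMAL)


@dataclass
class WorkbookData:
    records: list
    rejects: list
    encoding: str = "utf-8"


def read_workbook(path, config: Optional[DialectConfig] = None) -> WorkbookData:
    """Read a DS4 workbook as-is (no FINAL resolution; see
    :func:`atcmap.pipeline.import_validation_workbook`).

    ``CORRECT`` and ``FINAL`` accept ATC codes truncated to level 3 or 4 as
    well as the labels ``nomed`` / ``unspec`` / ``no_eval``; malformed codes
    quarantine the row.
    """
    from .atc import LABELS

    config = config or DialectConfig()
    frame, encoding = _read_table(path, config)
    _require(frame, config, DS4_COLUMNS, path)
    records: list[ValidationRecord] = []
    rejects: list[RejectedRow] = []
    for row_number, row in enumerate(frame.to_dict("records"), start=2):
        try:
            correct = row[config.name("CORRECT")].strip()
            final = row[config.name("FINAL")].strip()
            if correct:
                code = AtcCode(correct)
                if code.level < 3:
                    raise AtcValidationError(f"CORRECT {correct!r} below ATC level 3")
                correct = str(code)
            if final and final not in LABELS:
                code = AtcCode(final)
                if code.level < 3:
                    raise AtcValidationError(f"FINAL {final!r} below ATC level 3")
                final = str(code)
            records.append(
                ValidationRecord(
                    medication=row[config.name("MEDICATION")],
                    frequency=int(row[config.name("FREQUENCY")]),
                    step1=_parse_opt_atc(row[config.name("Step1")]),
                    step2=_parse_opt_atc(row[config.name("Step2")]),
                    step3=_parse_step3(row[config.name("Step3")]),
                    eval1=_parse_bool(row[config.name("Eval1")]),
                    eval2=_parse_bool(row[config.name("Eval2")]),
                    eval3=_parse_bool(row[config.name("Eval3")]),
                    true12=bool(_parse_bool(row[config.name("True12")])),
                    true13=bool(_parse_bool(row[config.name("True13")])),
                    true23=bool(_parse_bool(row[config.name("True23")])),
                    true123=bool(_parse_bool(row[config.name("True123")])),
                    correct=correct or None,
                    comments=row[config.name("COMMENTS")],
                    final=final or None,
                )
            )
        except (AtcValidationError, ValueError) as exc:
            rejects.append(RejectedRow(row_number, row, str(exc)))
    return WorkbookData(records, rejects, encoding)


def write_rejects(rejects: Sequence[RejectedRow], path, config: Optional[DialectConfig] = None) -> None:
    """Write quarantined rows with their reasons next to the main output."""
    config = config or DialectConfig()
    rows = [{"row_number": r.row_number, "reason": r.reason, **r.data} for r in rejects]
    pd.DataFrame(rows).to_csv(path, sep=config.sep, index=False)
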