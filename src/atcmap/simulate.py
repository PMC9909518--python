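"""Synthetic drug catalog and prescription generator with known ground truth.

Real hospital prescription tables cannot be shipped, so every stage of the
package is exercised on synthetic data that reproduces the *structural*
phenomena of such tables: a product catalog with pseudo drug names (built
from syllables, never a licensed list), dose/form decorations
("<NAME> 500 Filmtabletten"), combination products sharing an ingredient
name across distinct ATC codes; and a prescription stream mixing
structured catalog picks, non-medication order texts ("BGA", "BE", "BB"),
and free-text corruptions of catalog rows (ingredient-plus-dose, token
shuffles, truncations, character-level typos at a controlled indel
distance, and texts unrelated to their source row).  Free-text frequencies
follow a Zipf law so that a modest top-N covers most of the unstructured
mass, as it does in practice.

Every draw is governed by the single seed in :class:`FixtureSpec`; the
same spec always yields bit-identical data.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .atc import AtcCode, CatalogEntry, DrugCatalog, PrescriptionRecord, ValidationRecord

__all__ = [
    "FixtureSpec",
    "TextTruth",
    "GroundTruth",
    "generate_catalog",
    "generate_prescriptions",
    "evaluate_against_truth",
    "write_fixture_files",
]

_SYLLABLES = (
    "va lor tin mex ol pra zol cor dex ami bu fen sta din ket mar neo pan "
    "tra vex lis ran bi sol mid lon cy per flu gan tol ras vi nor dol"
).split()

_FORMS = (
    "Filmtabletten",
    "Tabletten",
    "Injektionslösung",
    "Zäpfchen",
    "Granulat",
    "Kapseln",
    "Infusionslösung",
    "Pulver",
)

_DOSES = (5, 10, 20, 25, 40, 50, 75, 100, 150, 200, 250, 300, 400, 500, 600, 750, 850, 1000)

#: Non-medication order texts; the leading-token ones are caught by the
#: default exclusion rules, the rest only surface in manual review.
_NOMED_RULED = (
    "BGA",
    "BE",
    "BB",
    "BGA kontrolle",
    "BGA 8:00",
    "BE morgen",
    "BE nüchtern",
    "BB heute",
    "BB abnehmen",
    "BGA arteriell",
    "BE 7:30",
    "BB kontrolle",
)
_NOMED_FREE = ("RR messen", "EKG schreiben", "Verband wechseln")

_CORRUPTION_CLASSES = (
    "verbatim_product",
    "ingredient_plus_dose",
    "token_shuffle",
    "truncation",
    "typo",
    "non_catalog_text",
)


def _default_mix() -> dict:
    return {
        "verbatim_product": 0.25,
        "ingredient_plus_dose": 0.30,
        "token_shuffle": 0.15,
        "truncation": 0.10,
        "typo": 0.10,
        "non_catalog_text": 0.10,
    }


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study population.

    Defaults emulate the study conditions the package is designed around: a
    prescription table that is 47.73% structured with 9.1% non-medication
    order texts, and a heavily skewed free-text frequency distribution.
    """

    n_catalog: int = 300
    n_prescriptions: int = 100_000
    structured_fraction: float = 0.4773
    nomed_fraction: float = 0.091
    combination_fraction: float = 0.10
    corruption_mix: dict = field(default_factory=_default_mix)
    n_unique_texts: int = 2000
    zipf_exponent: float = 1.5
    typo_k: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("structured_fraction", "nomed_fraction", "combination_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        unknown = set(self.corruption_mix) - set(_CORRUPTION_CLASSES)
        if unknown:
            raise ValueError(f"unknown corruption classes {sorted(unknown)}")
        total = sum(self.corruption_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"corruption mix must sum to 1, got {total}")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")


@dataclass(frozen=True)
class TextTruth:
    """Ground truth for one unique generated text: its true ATC level-5
    code (``None`` for non-medication texts, where ``label == 'nomed'``)
    and the corruption class that produced it."""

    atc: Optional[str]
    label: Optional[str]
    corruption: str


@dataclass
class GroundTruth:
    """Per-text truth plus the generator's own bookkeeping counts."""

    per_text: dict  # text -> TextTruth
    n_structured: int = 0
    n_nomed: int = 0
    n_unstructured: int = 0
    level1_counts: Counter = field(default_factory=Counter)  # truth by ATC level 1

    def truth_for(self, text: str) -> Optional[TextTruth]:
        return self.per_text.get(text)


def _pseudo_word(rng: np.random.Generator, n_syllables: int) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(n_syllables))


def _random_atc(rng: np.random.Generator) -> AtcCode:
    letters = sorted("ABCDGHJLMNPRSV")
    code = (
        rng.choice(letters)
        + f"{rng.integers(0, 100):02d}"
        + "".join(chr(ord("A") + rng.integers(0, 26)) for _ in range(2))
        + f"{rng.integers(0, 100):02d}"
    )
    return AtcCode(code)


def generate_catalog(spec: FixtureSpec) -> DrugCatalog:
    """Generate a DS2-shaped catalog of pseudo drug products.

    A ``combination_fraction`` share of entries (Bernoulli per entry, once
    a few base entries exist) reuses an existing ingredient name under a
    *distinct* ATC code and a "comp" product name — the combination-product
    trap that misleads similarity matching in real data.
    """
    if spec.n_catalog < 1:
        raise ValueError("n_catalog must be >= 1")
    rng = np.random.default_rng([spec.seed, 0])
    entries: list[CatalogEntry] = []
    used_atc: set[str] = set()
    used_ingredients: list[str] = []
    used_products: set[str] = set()
    while len(entries) < spec.n_catalog:
        atc = _random_atc(rng)
        if str(atc) in used_atc:
            continue
        is_comb = len(used_ingredients) >= 10 and rng.random() < spec.combination_fraction
        if is_comb:
            ingredient = used_ingredients[int(rng.integers(0, len(used_ingredients)))]
            product = (
                f"{ingredient.upper()} comp {int(rng.choice(_DOSES))} mg "
                f"{rng.choice(_FORMS)}"
            )
        else:
            ingredient = _pseudo_word(rng, int(rng.integers(2, 5))).capitalize()
            if any(ingredient == i for i in used_ingredients):
                continue
            product = f"{ingredient.upper()} {int(rng.choice(_DOSES))} {rng.choice(_FORMS)}"
        if product in used_products:
            continue
        used_atc.add(str(atc))
        used_products.add(product)
        if not is_comb:
            used_ingredients.append(ingredient)
        entries.append(CatalogEntry(product, ingredient, atc))
    return DrugCatalog(entries)


def _render(
    rng: np.random.Generator, entry: CatalogEntry, corruption: str, typo_k: int
) -> str:
    product, ingredient = entry.product_name, entry.ingredient_name
    if corruption == "verbatim_product":
        return product
    if corruption == "ingredient_plus_dose":
        return f"{ingredient} {int(rng.choice(_DOSES))}"
    if corruption == "token_shuffle":
        tokens = product.split()
        order = rng.permutation(len(tokens))
        return " ".join(tokens[i] for i in order)
    if corruption == "truncation":
        tokens = product.split()
        keep = max(1, int(rng.integers(1, 3)))
        return " ".join(tokens[:keep])
    if corruption == "typo":
        text = list(product)
        for _ in range(typo_k):
            if len(text) > 2 and rng.random() < 0.5:
                del text[int(rng.integers(0, len(text)))]
            else:
                pos = int(rng.integers(0, len(text) + 1))
                text.insert(pos, chr(ord("a") + int(rng.integers(0, 26))))
        return "".join(text)
    if corruption == "non_catalog_text":
        return f"{_pseudo_word(rng, 3)} {int(rng.integers(1, 99))} Schema"
    raise ValueError(f"unknown corruption class {corruption!r}")


def generate_prescriptions(
    catalog: DrugCatalog, spec: FixtureSpec
) -> tuple[list[PrescriptionRecord], GroundTruth]:
    """Generate a DS1-shaped prescription stream with ground truth.

    Structured records reference real catalog rows (drop-down style
    "<PRODUCT> | (<ingredient>)" text, ATC present); unstructured records
    draw from a Zipf-weighted pool of corrupted renderings; non-medication
    records draw from an order-text vocabulary, most of it caught by the
    default exclusion rules.
    """
    if len(catalog) == 0:
        raise ValueError("catalog must be non-empty")
    rng = np.random.default_rng([spec.seed, 1])
    entries = catalog.entries

    # unique free-text pool with truth
    per_text: dict[str, TextTruth] = {}
    classes = list(spec.corruption_mix)
    class_p = np.array([spec.corruption_mix[c] for c in classes])
    pool: list[str] = []
    while len(pool) < spec.n_unique_texts:
        entry = entries[int(rng.integers(0, len(entries)))]
        corruption = classes[int(rng.choice(len(classes), p=class_p))]
        text = _render(rng, entry, corruption, spec.typo_k)
        if text in per_text:
            continue  # retry with fresh draws; pool texts must be unique
        per_text[text] = TextTruth(str(entry.atc_code), None, corruption)
        pool.append(text)
    nomed_vocab = [t for t in (*_NOMED_RULED, *_NOMED_FREE) if t not in per_text]
    for text in nomed_vocab:
        per_text[text] = TextTruth(None, "nomed", "nomed")

    # Zipf weights over a random permutation of the pool
    ranks = rng.permutation(len(pool)) + 1
    weights = 1.0 / ranks.astype(float) ** spec.zipf_exponent
    weights /= weights.sum()
    catalog_ranks = rng.permutation(len(entries)) + 1
    catalog_weights = 1.0 / catalog_ranks.astype(float) ** spec.zipf_exponent
    catalog_weights /= catalog_weights.sum()

    truth = GroundTruth(per_text=per_text)
    records: list[PrescriptionRecord] = []
    u = rng.random(spec.n_prescriptions)
    years = rng.integers(2016, 2021, size=spec.n_prescriptions)
    structured_idx = rng.choice(len(entries), size=spec.n_prescriptions, p=catalog_weights)
    pool_idx = rng.choice(len(pool), size=spec.n_prescriptions, p=weights)
    nomed_idx = rng.integers(0, len(nomed_vocab), size=spec.n_prescriptions)
    for i in range(spec.n_prescriptions):
        year = int(years[i])
        if u[i] < spec.structured_fraction:
            entry = entries[int(structured_idx[i])]
            text = f"{entry.product_name} | ({entry.ingredient_name})"
            records.append(PrescriptionRecord(text, year, True, entry.atc_code))
            truth.n_structured += 1
            truth.level1_counts[str(entry.atc_code.truncate(1))] += 1
        elif u[i] < spec.structured_fraction + spec.nomed_fraction:
            records.append(PrescriptionRecord(nomed_vocab[int(nomed_idx[i])], year, False))
            truth.n_nomed += 1
        else:
            text = pool[int(pool_idx[i])]
            records.append(PrescriptionRecord(text, year, False))
            truth.n_unstructured += 1
            truth.level1_counts[per_text[text].atc[:1]] += 1
    return records, truth


def evaluate_against_truth(
    workbook: Sequence[ValidationRecord], truth: GroundTruth
) -> list[ValidationRecord]:
    """Synthetic reviewer: fill the manual-evaluation fields of DS4 rows
    from generator ground truth.

    Marks each algorithm result correct/wrong against the text's true ATC;
    when no algorithm found it, enters the truth in CORRECT — except for
    texts rendered unrelated to their source row (``non_catalog_text``),
    where a real reviewer could not recover the code either and the row is
    flagged ``unspec``.  Non-medication texts get FINAL ``nomed``.  Texts
    unknown to the generator are left untouched (they resolve to
    ``no_eval``).
    """
    for record in workbook:
        t = truth.truth_for(record.medication)
        if t is None:
            continue
        if t.label == "nomed":
            record.final = "nomed"
            record.comments = "synthetic reviewer: order text, not a medication"
            continue
        top3 = record.step3_top
        record.eval1 = None if record.step1 is None else str(record.step1) == t.atc
        record.eval2 = None if record.step2 is None else str(record.step2) == t.atc
        record.eval3 = None if top3 is None else str(top3.atc) == t.atc
        if not (record.eval1 or record.eval2 or record.eval3):
            if t.corruption == "non_catalog_text":
                record.final = "unspec"
                record.comments = "synthetic reviewer: text too unspecific to resolve"
            else:
                record.correct = t.atc
                record.comments = "synthetic reviewer: entered manually"
    return list(workbook)


def write_fixture_files(spec: FixtureSpec, out_dir) -> dict:
    """Generate and write a DS1 file, a DS2 file and a ground-truth sidecar
    (plus a JSON provenance file recording the spec); returns the paths."""
    import pandas as pd

    from .io import write_catalog, write_prescriptions

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = generate_catalog(spec)
    records, truth = generate_prescriptions(catalog, spec)
    paths = {
        "ds1": out / "ds1_prescriptions.csv",
        "ds2": out / "ds2_catalog.csv",
        "truth": out / "ground_truth.csv",
        "provenance": out / "fixture_spec.json",
    }
    write_prescriptions(records, paths["ds1"])
    write_catalog(catalog, paths["ds2"])
    pd.DataFrame(
        [
            {
                "MEDICATION": text,
                "truth_atc": t.atc or "",
                "label": t.label or "",
                "corruption": t.corruption,
            }
            for text, t in truth.per_text.items()
        ]
    ).to_csv(paths["truth"], index=False)
    paths["provenance"].write_text(json.dumps(asdict(spec), indent=2, ensure_ascii=False))
    return paths
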