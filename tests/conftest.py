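"""Shared fixtures and independent oracles for the test suite."""

import hypothesis
import pytest

from atcmap.atc import AtcCode, CatalogEntry, DrugCatalog, PrescriptionRecord
from atcmap.simulate import FixtureSpec, generate_catalog, generate_prescriptions

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=100, deadline=None
)
hypothesis.settings.load_profile("default")


def indel_oracle(a: str, b: str) -> int:
    """Brute-force dynamic-programming insertion/deletion edit distance.

    Independent of the package's bit-parallel LCS path: a full DP table
    over the classic recurrence with unit insert/delete costs and no
    substitution move.
    """
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1]
            else:
                cur[j] = min(prev[j], cur[j - 1]) + 1
        prev = cur
    return prev[-1]


@pytest.fixture(scope="session")
def catalog() -> DrugCatalog:
    """Hand-built mini catalog covering the interesting shapes: plain
    products, a combination product sharing its ingredient name with a
    single-ingredient product (ambiguity trap), and German decorations."""
    entries = [
        CatalogEntry("IBUPROFEN STADA 600 mg Zäpfchen", "Ibuprofen", AtcCode("M01AE01")),
        CatalogEntry("PARACETAMOL STADA 500 mg Tabletten", "Paracetamol", AtcCode("N02BE01")),
        CatalogEntry("ARILIN 500 Filmtabletten", "Metronidazol", AtcCode("P01AB01")),
        CatalogEntry("PREDNISOLON 5 mg Tabletten", "Prednisolon", AtcCode("H02AB06")),
        CatalogEntry("NACL 0.9% Infusionslösung", "Natriumchlorid", AtcCode("B05BB11")),
        CatalogEntry("METAMIZOL 500 Tropfen", "Metamizol", AtcCode("N02BB02")),
        CatalogEntry("CANDESARTAN 8 mg Tabletten", "Candesartan", AtcCode("C09CA06")),
        CatalogEntry("CANDESARTAN comp 16 mg Tabletten", "Candesartan", AtcCode("C09DA26")),
    ]
    return DrugCatalog(entries)


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    return FixtureSpec(
        n_catalog=150, n_prescriptions=20_000, n_unique_texts=600, seed=11
    )


@pytest.fixture(scope="session")
def small_corpus(small_spec):
    """A modest synthetic corpus shared across tests: catalog, records,
    ground truth."""
    cat = generate_catalog(small_spec)
    records, truth = generate_prescriptions(cat, small_spec)
    return cat, records, truth
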