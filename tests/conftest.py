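import numpy as np
import pytest

from codonforge import (
    OrganismRegistry,
    TranslationTable,
    UsageTable,
    build_vocabulary,
)


@pytest.fixture(scope="session")
def standard_table() -> TranslationTable:
    return TranslationTable.from_ncbi(1)


@pytest.fixture(scope="session")
def bacterial_table() -> TranslationTable:
    return TranslationTable.from_ncbi(11)


@pytest.fixture(scope="session")
def vocab(standard_table):
    return build_vocabulary(standard_table)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def toy_usage(standard_table) -> UsageTable:
    """Hand-set counts with known ratios: Lys 8:2, Ala 6:2:1:1, Asn tie."""
    counts = {c: 5.0 for c in standard_table.codon_to_aa}
    counts.update(
        {
            "AAA": 8.0,
            "AAG": 2.0,  # Lys: w = 1, 0.25
            "GCC": 6.0,
            "GCA": 2.0,
            "GCG": 1.0,
            "GCT": 1.0,  # Ala
            "AAT": 5.0,
            "AAC": 5.0,  # Asn tie
        }
    )
    return UsageTable.from_counts(counts, standard_table, organism="toy")


@pytest.fixture(scope="session")
def registry() -> OrganismRegistry:
    reg = OrganismRegistry()
    reg.add("orgA")
    reg.add("orgB")
    return reg
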