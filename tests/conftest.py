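import numpy as np
import pytest

from sexlinkscan.datamodel import AmpliconDef, Compartment, GenotypeRecord, Sex
from sexlinkscan.synthdata import SimConfig, assemble_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset shared across tests."""
    return assemble_dataset(SimConfig(seed=42))


@pytest.fixture
def tiny_panel():
    return [
        AmpliconDef("ampA", "chr2", 101, 110, 10),
        AmpliconDef("ampB", "chr2", 201, 212, 12),
    ]


@pytest.fixture
def tiny_phenotypes():
    recs = []
    for i in range(3):
        recs.append(GenotypeRecord(f"f{i}", Sex.FEMALE, Compartment.WILD))
    for i in range(3):
        recs.append(GenotypeRecord(f"m{i}", Sex.MALE, Compartment.WILD))
    recs.append(GenotypeRecord("h0", Sex.HERMAPHRODITE, Compartment.DOMESTICATED))
    return recs


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
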