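import numpy as np
import pytest

from hlavb import AlleleDatabase, AlleleRecord, generate_synthetic_panel, parse_allele_name


@pytest.fixture(scope="session")
def panel() -> AlleleDatabase:
    """Default hierarchical synthetic panel: 6 loci x 12 alleles, 1 kb."""
    return generate_synthetic_panel(seed=42)


@pytest.fixture(scope="session")
def tiny_panel() -> AlleleDatabase:
    """Two well-separated alleles at one locus, handy for exact checks."""
    rng = np.random.default_rng(7)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq_a = bases[rng.integers(0, 4, 400)].tobytes().decode()
    seq_b = bases[rng.integers(0, 4, 400)].tobytes().decode()
    return AlleleDatabase(records=[
        AlleleRecord(name=parse_allele_name("X*01:01"), sequence=seq_a),
        AlleleRecord(name=parse_allele_name("X*02:01"), sequence=seq_b),
    ])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
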