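from pathlib import Path

import numpy as np
import pytest

from promiscreen import (
    MsaSpec,
    PlantedColumn,
    SignatureCriterion,
    generate_msa,
    read_alignment,
)

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy5():
    """Hand-authored 5-sequence alignment: signature H/P at position 4,
    one planted shifted column at position 8 (A in the P class, S in the
    H class)."""
    return read_alignment(DATA / "toy5.fasta", reference_id="seq1")


@pytest.fixture(scope="session")
def toy5_criterion():
    return SignatureCriterion(4, {"H"}, {"P"})


@pytest.fixture(scope="session")
def planted_msa():
    """Synthetic MSA with three planted signature-coupled columns."""
    spec = MsaSpec(
        n_seq=400,
        length=60,
        planted=[
            PlantedColumn(10, "A", "S", 0.6),
            PlantedColumn(20, "L", "F", 0.6),
            PlantedColumn(40, "K", "E", 0.6),
        ],
        seed=1,
    )
    return generate_msa(spec), spec


@pytest.fixture(scope="session")
def signature_criterion():
    return SignatureCriterion(34, {"H"}, {"P"})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
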