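import numpy as np
import pytest

from morfpssm import ProteinRecord, ScoreMatrix, SimulationConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def random_raw_matrix(rng):
    """A 30-residue raw matrix with PSI-BLAST-range integer scores."""
    values = rng.integers(-10, 13, size=(30, 20)).astype(float)
    return ScoreMatrix("p1", values, stage="raw")


@pytest.fixture
def annotated_protein():
    return ProteinRecord(id="p1", sequence="ACDEFGHIKLMNPQRSTVWY" * 3,
                         morf_intervals=[(10, 20), (35, 44)])


@pytest.fixture(scope="session")
def small_simulation():
    """Ten seeded proteins with matrices, shared across read-only tests."""
    return simulate(SimulationConfig(n_proteins=10, length_range=(40, 80), seed=77))
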