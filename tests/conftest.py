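import numpy as np
import pytest

from dsrpipe.io_formats import ProteinSequence
from dsrpipe.synthetic_data import SimulationConfig, simulate_dataset

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int, pid: str = "p",
                   genome: str = "", genus: str = "") -> ProteinSequence:
    seq = "".join(AA[i] for i in rng.integers(0, 20, length))
    return ProteinSequence(pid, seq, genome, genus)


@pytest.fixture(scope="session")
def small_dataset():
    """A 10-genome dataset with short sequences, shared across tests."""
    config = SimulationConfig(
        seed=42, n_genomes=10, seq_length=120, cargo_length=80, n_cargo=4
    )
    genomes, truth = simulate_dataset(config)
    return config, genomes, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
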