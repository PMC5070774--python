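import numpy as np
import pytest

from haplospread.alignment import Alignment
from haplospread.simulate import SimulationParams, simulate


def random_alignment(rng, n_seqs, length, alphabet="ACGT", missing_rate=0.0):
    """Random test alignment; optional gap/N noise."""
    chars = np.array(list(alphabet + ("N-" if missing_rate else "")))
    base = rng.choice(list(alphabet), size=(n_seqs, length))
    if missing_rate:
        mask = rng.random((n_seqs, length)) < missing_rate
        noise = rng.choice(list("N-"), size=(n_seqs, length))
        base = np.where(mask, noise, base)
    del chars
    return Alignment.from_records(
        (f"s{i + 1}", "".join(row)) for i, row in enumerate(base)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sweep_dataset():
    return simulate(SimulationParams(scenario="sweep"), seed=7)


@pytest.fixture(scope="session")
def introgression_dataset():
    return simulate(SimulationParams(scenario="introgression"), seed=7)
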