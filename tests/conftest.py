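import numpy as np
import pytest

from msddseq import digest, simdata


@pytest.fixture(scope="session")
def registry():
    return digest.default_registry()


@pytest.fixture(scope="session")
def small_experiment():
    """One modest simulated experiment shared by read-level tests."""
    cfg = simdata.SimulationConfig(
        seed=7, genome_length=60_000, n_differential_loci=8
    )
    return simdata.simulate_experiment(cfg)


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(np.array(list("ACGT")), size=n))
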