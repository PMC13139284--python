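import numpy as np
import pytest

from mtqsar import featurize, simdata


@pytest.fixture(scope="session")
def small_spec():
    return simdata.SimulationSpec(
        n_compounds=120, n_tasks=4, sparsity=0.5, noise_sd=0.2,
        planted_rules=simdata.default_rules(4),
        duplicate_rate=0.08, salt_rate=0.08, seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return simdata.simulate(small_spec)


@pytest.fixture(scope="session")
def small_fps(small_dataset):
    return featurize.fingerprint_matrix(small_dataset.molecules)


@pytest.fixture(scope="session")
def molecule_pool():
    """A reusable pool of valid synthetic molecules."""
    return simdata.generate_molecules(80, seed=3)
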