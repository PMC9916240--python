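import numpy as np
import pytest

from omstab.coupling import fit_coupled
from omstab.synthetic import GeneratorParams, generate_dataset

DEFAULT_HOLDOUT = ("W01", "W26")


@pytest.fixture(scope="session")
def default_params():
    return GeneratorParams()


@pytest.fixture(scope="session")
def study_seed1(default_params):
    """The default study-shaped synthetic dataset, seed 1."""
    return generate_dataset(default_params, seed=1)


@pytest.fixture(scope="session")
def coupled_seed1(study_seed1):
    """Coupled model fitted on the seed-1 study with the default holdout."""
    return fit_coupled(study_seed1, holdout_families=DEFAULT_HOLDOUT)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
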