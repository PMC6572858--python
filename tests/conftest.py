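import numpy as np
import pytest

from luxsat import synthetic_data as sd


@pytest.fixture(scope="session")
def truth_params() -> sd.TruthParams:
    """Default ground-truth light-response parameters."""
    return sd.TruthParams()

@pytest.fixture(scope="session")
def noiseless_params() -> sd.TruthParams:
    return sd.TruthParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def design_grid() -> sd.DesignGrid:
    """The 7 x 6 x 10 nested design."""
    return sd.default_design_grid()


@pytest.fixture(scope="session")
def noiseless_samples(design_grid, noiseless_params):
    return sd.simulate_dataset(design_grid, noiseless_params, seed=11)


@pytest.fixture(scope="session")
def noisy_samples(design_grid, truth_params):
    return sd.simulate_dataset(design_grid, truth_params, seed=11)
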