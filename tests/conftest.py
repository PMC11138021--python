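import numpy as np
import pytest

from csfoi import synthetic


@pytest.fixture(scope="session")
def b_values():
    """The six-point CSF diffusion-weighting scheme, s/mm^2."""
    return np.array([0.0, 50.0, 100.0, 250.0, 500.0, 1000.0])


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small two-region noiseless DWI phantom with ground truth."""
    config = synthetic.SyntheticDWIConfig(
        grid_shape=(6, 4, 4), noise_model="none", seed=0
    )
    return synthetic.simulate_dwi(config)
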