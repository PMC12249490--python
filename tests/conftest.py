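import numpy as np
import pytest

from turnoverkit.kinetics import LabelingParameters
from turnoverkit.simulate import LabelingDesign, simulate_dataset


@pytest.fixture
def params():
    return LabelingParameters(p_w=0.04)


@pytest.fixture
def params_ph0():
    """Parameters with natural deuterium abundance neglected, as in the
    source analyses' numeric evaluations."""
    return LabelingParameters(p_w=0.04, p_h=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)


@pytest.fixture(scope="session")
def small_sim():
    """A small noisy simulated dataset shared by read-only tests."""
    design = LabelingDesign(
        n_proteins=5, peptides_per_protein=8, noise_sd_i0=0.002, p_h=0.0, seed=7
    )
    return design, *simulate_dataset(design)
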