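import numpy as np
import pytest

from bpvlab.design import HemodynamicModel, PKPDParams, StudyDesign


@pytest.fixture(scope="session")
def design():
    return StudyDesign(seed=7)


@pytest.fixture(scope="session")
def model():
    return HemodynamicModel()


@pytest.fixture(scope="session")
def quiet_model():
    """All stochastic and periodic terms switched off."""
    return HemodynamicModel(circadian_amplitude=0.0, day_effect_sd=0.0,
                            epoch_noise_sd=0.0, hr_noise_sd=0.0,
                            lf_amplitude=0.0, hf_ibi_amplitude=0.0,
                            ibi_jitter_sd=0.0, beat_sbp_noise_sd=0.0)


@pytest.fixture(scope="session")
def placebo_pk():
    return PKPDParams()   # no doses scheduled


@pytest.fixture
def rng():
    return np.random.default_rng(20150368)
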