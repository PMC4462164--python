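import pytest

from commetab import preset


@pytest.fixture
def co_culture_noiseless():
    """Wild-type co-culture preset with all measurement noise off."""
    return preset("co_culture", seed=1,
                  trace={"noise_sd_j": 0.0},
                  metabolite={"noise_sd_mM": 0.0},
                  flavin={"noise_sd_rfu": 0.0},
                  community={"image_noise_sd": 0.0})


@pytest.fixture
def mutant_noiseless():
    """Hydrogenase-mutant co-culture preset, noise off."""
    return preset("hydrogenase_mutant", seed=1, trace={"noise_sd_j": 0.0})
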