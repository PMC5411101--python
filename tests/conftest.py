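import pytest

from tfshare import ModelSpec, RegulationMode

# Measured E. coli kinetic rates used throughout (s^-1):
# binding 0.0027 per TF per promoter, unbinding 0.0023 per complex,
# transcription 0.33 per active promoter, mRNA decay 0.011 per molecule.
RATES = {"k_on": 0.0027, "k_off": 0.0023, "r": 0.33, "gamma": 0.011}


def make_spec(**overrides) -> ModelSpec:
    params = {"n_tf": 1, "mode": "activator", **RATES}
    params.update(overrides)
    return ModelSpec(**params)


@pytest.fixture
def activator_single():
    """Single promoter, single activator, no competitors."""
    return make_spec()


@pytest.fixture
def repressor_single():
    return make_spec(mode="repressor")


@pytest.fixture
def rates():
    return dict(RATES)
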