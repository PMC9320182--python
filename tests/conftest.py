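import numpy as np
import pytest

from aquarisk.campaign import CampaignConfig, generate_campaign
from aquarisk.reference import study_mean_concentrations


@pytest.fixture(scope="session")
def tw_means():
    """Published mean tap-water concentrations, mg/L."""
    return study_mean_concentrations("TW")


@pytest.fixture(scope="session")
def small_campaign():
    """Deterministic 72-sample synthetic campaign (study default design)."""
    return generate_campaign(CampaignConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
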