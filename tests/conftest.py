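import warnings

import pytest

from springwalker.dynamics import WalkerParams
from springwalker.periodic import find_stiffness_for_gait
from springwalker.pipeline import analyze_trial
from springwalker.synthetic import NoiseConfig, SyntheticConfig, generate_trial


@pytest.fixture(scope="session")
def params():
    return WalkerParams()


@pytest.fixture(scope="session")
def worked_gait(params):
    """The worked-example periodic gait with step length 0.6 and speed 0.39."""
    return find_stiffness_for_gait(0.6, 0.39, params)


@pytest.fixture(scope="session")
def noiseless_trial():
    """A measurement-noise-free synthetic trial (gait variability retained)."""
    config = SyntheticConfig(noise=NoiseConfig.zeros(), seed=1)
    return generate_trial(config)


@pytest.fixture(scope="session")
def noiseless_analysis(noiseless_trial):
    trial, _ = noiseless_trial
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_trial(trial)
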