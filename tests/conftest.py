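import numpy as np
import pytest

from sporeflux import synthetic


@pytest.fixture(scope="session")
def quarter_hour_times():
    """Sampling grid 0..6 h every 15 min."""
    return np.arange(0.0, 6.01, 0.25)


@pytest.fixture(scope="session")
def noiseless_scenario():
    return synthetic.SlurryScenario(noise_cv=0.0)


@pytest.fixture(scope="session")
def noiseless_timecourse(noiseless_scenario, quarter_hour_times):
    return synthetic.simulate_slurry_timecourse(
        noiseless_scenario, quarter_hour_times
    )
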