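import pytest

from startcea.cea_stats import calibrated
from startcea.param_model import load_default_parameters


@pytest.fixture(scope="session")
def base_params():
    """The packaged base-case parameter set (uncalibrated)."""
    return load_default_parameters()


@pytest.fixture(scope="session")
def calibrated_params(base_params):
    """Base case with the post-discharge initiation probability calibrated
    so the usual-care arm's 12-month QALYs hit the configured target."""
    return calibrated(base_params)
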