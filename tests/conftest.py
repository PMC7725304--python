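import pytest

from dmhapto.ap_model import ModelParams


@pytest.fixture
def default_params() -> ModelParams:
    """Printed default parameter set of the mechanistic model."""
    return ModelParams()


@pytest.fixture
def nominal_v0_params() -> ModelParams:
    """Defaults with the literal rounded resting-offset voltage."""
    return ModelParams(v0=55.0)
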