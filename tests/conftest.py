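import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rc_model():
    """The discrete-component test circuit: Rs=220, Rp=510, Cp=2.2 uF."""
    from stimbalance import ElectrodeTissueModel

    return ElectrodeTissueModel(220.0, 510.0, 2.2e-6)


@pytest.fixture
def slow_rc_model():
    """The charge-balance bench circuit: Rs=220, Rp=510, Cp=22 uF."""
    from stimbalance import ElectrodeTissueModel

    return ElectrodeTissueModel(220.0, 510.0, 22e-6)
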