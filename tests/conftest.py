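import pytest

from irristoch import compute_thresholds, constant_driver, default_params
from irristoch.payoff_model import ModelParams, calibrated_params


@pytest.fixture(scope="session")
def params():
    """Paper-default parameters with calibrated constants."""
    return default_params()


@pytest.fixture(scope="session")
def thresholds(params):
    return compute_thresholds(params)


@pytest.fixture(scope="session")
def small_params():
    """A down-scaled system (W/a = 100, anchors 7/33/70) for fast simulation.

    The responsiveness r is raised so the incentive term dominates the
    demographic noise floor at these small populations, mirroring the
    structure of the full-scale system.
    """
    base = ModelParams(a=0.01, r=50.0, dt=0.02)
    return calibrated_params((7, 33, 70), base)


@pytest.fixture(scope="session")
def calm_specs(params):
    return (
        constant_driver("lognormal", params.W_bar),
        constant_driver("beta", params.T_bar),
    )
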