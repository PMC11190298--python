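import pytest

from ducem import default_config
from ducem.maic import AggregateBaseline, estimate_weights
from ducem.synthetic import ANAPRAZOLE_PROFILE, ILAPRAZOLE_PROFILE, generate_ipd


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def anaprazole_ipd(cfg):
    """Synthetic anaprazole-arm IPD at the published margins (n=220)."""
    return generate_ipd(ANAPRAZOLE_PROFILE, seed=cfg.seed)


@pytest.fixture(scope="session")
def ilaprazole_target():
    return AggregateBaseline.from_profile(ILAPRAZOLE_PROFILE)


@pytest.fixture(scope="session")
def matched_weights(anaprazole_ipd, ilaprazole_target):
    return estimate_weights(anaprazole_ipd, ilaprazole_target)
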