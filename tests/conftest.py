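import numpy as np
import pytest

from kinteam.chemistry import RateParams
from kinteam.mechanics import MechanicalParams
from kinteam.rebinding import AttachmentProfile
from kinteam.unbinding import UnbindingParams


@pytest.fixture(scope="session")
def mech() -> MechanicalParams:
    return MechanicalParams()


@pytest.fixture(scope="session")
def rates() -> RateParams:
    return RateParams()


@pytest.fixture(scope="session")
def ubp() -> UnbindingParams:
    return UnbindingParams()


@pytest.fixture(scope="session")
def profile() -> AttachmentProfile:
    return AttachmentProfile()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
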