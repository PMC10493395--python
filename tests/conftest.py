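import numpy as np
import pytest

from secflux.models import LogisticParams
from secflux.traces import KineticTrace


@pytest.fixture
def ref_params() -> LogisticParams:
    """Reference kinetic parameter set used throughout the suite."""
    return LogisticParams(a=0.03, kappa=0.5, c=0.3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230828)


def make_trace(time, signal, **kw):
    defaults = dict(condition_id="cond", replicate=(1, 1))
    defaults.update(kw)
    return KineticTrace(time=np.asarray(time, float), signal=np.asarray(signal, float), **defaults)


@pytest.fixture
def linear_ramp_trace():
    t = np.linspace(0.0, 9.0, 10)
    return make_trace(t, np.linspace(0.0, 100.0, 10))
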