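import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dualcontrol import (
    HybridParams,
    RewardWalk,
    TransitionStructure,
    TwoStepSession,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


class ScriptedRNG:
    """Stands in for a Generator, returning a scripted sequence of uniforms."""

    def __init__(self, values):
        self.values = list(values)

    def uniform(self, *args, **kwargs):
        return self.values.pop(0)


@pytest.fixture
def structure():
    return TransitionStructure()


@pytest.fixture
def walk3():
    probs = np.array(
        [
            [0.25, 0.75, 0.50, 0.30],
            [0.40, 0.60, 0.70, 0.25],
            [0.30, 0.50, 0.45, 0.65],
        ]
    )
    return RewardWalk(probs=probs, sd_innovation=0.025)


@pytest.fixture
def spec_params():
    return HybridParams(
        beta1=2.0, beta2=2.0, alpha1=0.5, alpha2=0.5, lam=0.5, omega=0.5, rho=0.1
    )


@pytest.fixture
def three_trial_session(structure, walk3):
    return TwoStepSession.from_arrays(
        "fixture",
        a1=[0, 1, 0],
        s2=[0, 1, 1],
        a2=[1, 0, 0],
        r=[1, 0, 1],
        structure=structure,
        walk=walk3,
    )
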