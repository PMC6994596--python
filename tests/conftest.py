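"""Shared fixtures: the reference parameter sets used across the suite."""

import pytest

from repliage import DivisionParameters, RateParameters, SimulationCaps


@pytest.fixture(scope="session")
def reference_division():
    """Division parameters of the single-cell lifespan simulations."""
    return DivisionParameters(s=0.6370, re=0.2902)


@pytest.fixture(scope="session")
def reference_rates():
    """Rate parameters (g=1.1, k1=0.5, k2=0.1) at three resilience levels."""
    return {
        Q: RateParameters(g=1.1, k1=0.5, k2=0.1, Q=Q) for Q in (2.6, 2.8, 3.0)
    }


@pytest.fixture(scope="session")
def caps():
    return SimulationCaps()
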