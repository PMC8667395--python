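import math

import pytest

from gboins import BINOMIAL, QUASI_BINOMIAL, BoundaryParams, normal_family


@pytest.fixture
def binomial_family():
    return BINOMIAL


@pytest.fixture
def quasi_family():
    return QUASI_BINOMIAL


@pytest.fixture
def normal_plugin_family():
    return normal_family(plugin_value=0.22)


@pytest.fixture
def table1_binary_params():
    """Tabulation parameters for the binary endpoint at target 0.2."""
    return BoundaryParams(
        phi0=0.2, c1=math.log(1.05), c2=math.log(1.05) / 3
    )


@pytest.fixture
def table1_continuous_params():
    """Tabulation parameters for the continuous endpoint at target 0.2."""
    return BoundaryParams(phi0=0.2, c1=math.log(1.1), c2=math.log(1.1) / 3)
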