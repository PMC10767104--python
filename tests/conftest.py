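import math

import pytest

from sutterbyflow import ChannelGeometry, DimensionlessParams, cross_section


@pytest.fixture
def baseline_params():
    """The default (baseline) operating point."""
    return DimensionlessParams()


@pytest.fixture
def baseline_geom():
    return ChannelGeometry()


@pytest.fixture
def baseline_section(baseline_geom):
    return cross_section(0.4, 0.2, baseline_geom)


@pytest.fixture
def flat_section():
    """Flat symmetric channel [-1, 1] with flow rate 2 (closed-form regime)."""
    geom = ChannelGeometry(a=0.0, b=0.0, m=0.0, omega=0.0, Theta=2.0)
    return cross_section(0.3, 0.1, geom)


@pytest.fixture
def decoupled_params():
    """All couplings off: cubic/linear closed forms solve the full system."""
    return DimensionlessParams(
        M=0.0, G_R=0.0, G_C=0.0, E_C=0.0, Pr=1.0, N_T=0.0, N_B=0.0,
        K_R=0.0, beta_F=0.05,
    )


@pytest.fixture
def table_fixed_params():
    """Held-fixed values accompanying the benchmark Nusselt table."""
    return DimensionlessParams(
        Pr=21.0, G_C=0.2, G_R=0.2, K_R=0.5, Sc=0.6, E_C=0.1,
        N_T=1.0, N_B=0.5, M=1.0, beta_e=0.1, beta_i=0.1, beta_F=1.0,
    )


@pytest.fixture
def reference_omega_geom():
    """Geometry of the printed-series set (omega = pi/3)."""
    return ChannelGeometry(a=0.3, b=0.3, m=0.2, omega=math.pi / 3, Theta=1.4)
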