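import numpy as np
import pytest

from airwaymorph import (ChallengeProtocol, ConstituentFields, GrownGeometry,
                         MaterialParams, RateParams, SimulationConfig)


@pytest.fixture(scope="session")
def mat():
    return MaterialParams()


@pytest.fixture(scope="session")
def rates():
    return RateParams()


@pytest.fixture()
def geom(rates):
    return GrownGeometry.reference(1.8, 1.9, 2.3, 101)


@pytest.fixture()
def fields(rates, geom):
    return ConstituentFields.homeostatic(rates, geom)


@pytest.fixture()
def neo_mat():
    """Homogeneous neo-Hookean material: no fibres, no active tone."""
    return MaterialParams(k1_c=0.0, k1_e=0.0, T_c=0.0)


@pytest.fixture()
def neo_fields(geom):
    """Pure ground-matrix wall (same solid fraction in both layers)."""
    n = geom.xi_outer_layer.size
    return ConstituentFields(
        phi_c=np.zeros(n), phi_p=np.zeros(n), phi_e=np.full(n, 0.3),
        phi_e_inner=np.full(geom.xi_inner_layer.size, 0.3))


def coarse_config(**overrides):
    """Short/coarse simulation config for fast protocol tests."""
    defaults = dict(
        nodes_per_layer=51, dt=0.1,
        protocol=ChallengeProtocol.periodic(omega=0.2, horizon=150.0),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture()
def coarse_cfg_factory():
    return coarse_config
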