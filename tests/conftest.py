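import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pbrflash as pf

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tangent_geom():
    return pf.make_geometry("tangent")


@pytest.fixture(scope="session")
def concentric_geom():
    return pf.make_geometry("concentric")


@pytest.fixture(scope="session")
def plain_geom():
    return pf.make_geometry("plain")


@pytest.fixture(scope="session")
def tangent_field(tangent_geom):
    """Calibrated default tangent scenario (30 deg downward, 0.7 vvm)."""
    aer = pf.AerationSpec(direction_deg=-30.0, rate_vvm=0.7)
    return pf.default_scenario(
        tangent_geom, aer, peak_vr_target=0.045, mean_tke_target=80.0
    )


@pytest.fixture()
def solid_body_field(plain_geom):
    """Solid-body rotation u_theta = omega*r on a plain disc, no wall taper.

    omega is expressed in (m/s)/mm so that streamfunction units match the
    generator's convention; the bilinear/central-difference machinery is
    exact for this quadratic streamfunction / linear velocity field.
    """
    omega = 5e-4  # (m/s)/mm  -> speed 0.05 m/s at r=100 mm
    from pbrflash.synthetic_flow import field_from_streamfunction, make_grid

    depth, lateral, mask = make_grid(plain_geom, spacing=2.0)
    D, L = np.meshgrid(depth, lateral, indexing="ij")
    psi = -0.5 * omega * (D * D + L * L)
    fld = field_from_streamfunction(plain_geom, psi, depth, lateral, mask)
    fld.omega = omega
    return fld
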