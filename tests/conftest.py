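"""Shared fixtures: coarse reference simulations reused across tests.

All fixtures are generated programmatically; the heavy ones are
session-scoped so each configuration is simulated once.
"""

from __future__ import annotations

import numpy as np
import pytest

import spherochip as sc
from spherochip.config import SolverOptions
from spherochip.design_space import DesignPoint
from spherochip.transport import TransportProperties

#: Coarse desk-scale settings used by the qualitative fixtures.
COARSE = SolverOptions(resolution_um=20.0, t_end_s=7200.0, dt_s=5.0)
DRUG = TransportProperties()


@pytest.fixture(scope="session")
def ref_dsc_run():
    """Reference DSC design (all connectors 60 um, R=120), Q1=Q2=0.01 ml/h."""
    d = sc.decode_name("P5.Wr6.R12.Hr6.Wl6.Hl6", q1=0.01, q2=0.01)
    return sc.simulate_design(d, solver=COARSE, props=DRUG)


@pytest.fixture(scope="session")
def ref_ssc_run():
    """Matched SSC design (left connector closed), Q=0.01 ml/h."""
    d = sc.decode_name("P5.Wr6.R12.Hr6.Wl0.Hl0", q2=0.01)
    return sc.simulate_design(d, solver=COARSE, props=DRUG)


@pytest.fixture(scope="session")
def unequal_dsc_run():
    """Reference DSC design with unequal supply rates, Q1 = 2 Q2."""
    d = sc.decode_name("P5.Wr6.R12.Hr6.Wl6.Hl6", q1=0.02, q2=0.01)
    return sc.simulate_design(d, solver=COARSE, props=DRUG)


@pytest.fixture(scope="session")
def duct_flow_10um():
    """Straight 200x100 um duct at 0.01 ml/h, 10 um voxels."""
    grid = sc.duct_grid(length_um=200, width_um=200, height_um=100, spacing_um=10)
    flow = sc.solve_flow(grid, bc=sc.FlowBC(q2_ml_h=0.01))
    return grid, flow


def make_design(**kw) -> DesignPoint:
    base = dict(q1=0.01, q2=0.01, wl=60.0, wr=60.0, hl=60.0, hr=60.0,
                radius=120.0, phi=0.5)
    base.update(kw)
    return DesignPoint(**base)
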