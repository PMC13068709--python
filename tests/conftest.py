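"""Shared fixtures: coarse test devices and the two case-study pipelines."""

import numpy as np
import pytest

from rfetsense.device import Device, DeviceSpec, MaterialParams, program_polarity
from rfetsense.probes import make_fixture
from rfetsense.response import current_vs_fraction, default_interface_condition

#: coarse mesh for unit tests — behavior-preserving, fast
COARSE_MESH = dict(mesh_nx=101, mesh_ny=16)


@pytest.fixture(scope="session")
def silicon():
    return MaterialParams()


@pytest.fixture(scope="session")
def symmetric_materials():
    return MaterialParams.symmetric()


@pytest.fixture(scope="session")
def coarse_device(silicon):
    return Device(DeviceSpec(**COARSE_MESH), silicon)


@pytest.fixture(scope="session")
def coarse_symmetric_device(symmetric_materials):
    return Device(DeviceSpec(**COARSE_MESH), symmetric_materials)


@pytest.fixture(scope="session")
def case_study_curves(silicon):
    """Current-vs-fraction curves for both case studies on the full device.

    Computed once per session at the nominal mesh; shared by the sensing
    and parameter-recovery tests.
    """
    device = Device(DeviceSpec(), silicon)
    fractions = np.linspace(0.0, 1.0, 11)
    curves = {}
    for case_id, sign in (("aptamer_cea", "p"), ("protease_inhibitor", "n")):
        fixture = make_fixture(case_id)
        cond = default_interface_condition(case_id)
        protocol = program_polarity(sign)
        curves[case_id] = (
            fixture,
            current_vs_fraction(device, protocol, fixture, cond, fractions))
    return curves
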