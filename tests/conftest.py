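"""Shared fixtures: coarse steady-state tips reused across the suite.

The steady tip solves are the expensive computations; one per Poisson
ratio at sigma/20 resolution is shared session-wide (the tip model is
deterministic, so sharing is safe).
"""
from __future__ import annotations

import numpy as np
import pytest

import pombetip as pt

COARSE_SPACING = 0.05  # sigma/20 for sigma = 1


@pytest.fixture(scope="session")
def unit_material():
    """Material with lumped rate G_max P / (E delta) = 1 (shape-neutral)."""
    return pt.WallMaterial(P=1.0, E=1.0, delta=1.0, nu=0.5, g_max=1.0)


@pytest.fixture(scope="session")
def unit_material_nu0():
    return pt.WallMaterial(P=1.0, E=1.0, delta=1.0, nu=0.0, g_max=1.0)


@pytest.fixture(scope="session")
def gaussian_signal():
    return pt.GrowthSignal(sigma=1.0)


@pytest.fixture(scope="session")
def steady_tip_nu05(gaussian_signal, unit_material):
    """(contour, metrics) for nu = 0.5 at coarse resolution."""
    return pt.steady_state_tip(
        gaussian_signal, unit_material, spacing=COARSE_SPACING
    )


@pytest.fixture(scope="session")
def steady_tip_nu0(gaussian_signal, unit_material_nu0):
    return pt.steady_state_tip(
        gaussian_signal, unit_material_nu0, spacing=COARSE_SPACING
    )


@pytest.fixture(scope="session")
def stencil(steady_tip_nu05):
    contour, metrics = steady_tip_nu05
    sigma_gz = 3.2 / metrics.alpha  # wild-type diameter 3.2 um
    return pt.make_stencil(sigma_gz, contour)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
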