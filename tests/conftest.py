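"""Shared fixtures: the cubic-crystal reference model and the expensive
session-scoped computations reused across test modules."""
import numpy as np
import pytest

import oriscat as osc

#: q below 2*pi/L (L = model edge) is the finite-model forward-scattering
#: regime; the bulk S <-> g transforms exclude it (see docs/methods.md).
FORWARD_CUT = 2.0 * np.pi / 35.0
RHO_B = 1000.0 / 35.0 ** 3


@pytest.fixture(scope="session")
def crystal10():
    """10x10x10 simple cubic lattice, a = 3.5 nm, centered, periodic box 35 nm."""
    return osc.cubic_crystal(3.5, (10, 10, 10))


@pytest.fixture(scope="session")
def sq100(crystal10):
    """Debye structure factor of the crystal up to 100 nm^-1, with the
    forward-scattering regime replaced by S = 1."""
    dq = 0.02
    q = np.arange(dq, 100.0 + dq / 2, dq)
    sq = osc.s_q_from_model(crystal10, q)
    S = np.where(q < FORWARD_CUT, 1.0, sq.S)
    return osc.StructureFactorCurve(q, S, crystal10.n)


@pytest.fixture(scope="session")
def graphene_image():
    """Single-orientation 2D pattern of the 25x25 graphene sheet (beam along y)."""
    sheet = osc.graphene_sheet(25, 25)
    grid = osc.fill_grid(sheet, 36.0, 40)
    img = osc.single_orientation_pattern(grid, 128, 34.0)
    return img


@pytest.fixture(scope="session")
def sphere_crystal_curve(crystal10):
    """Intensity of the sphere-decorated crystal, I = N |f|^2 S, on [0.1, 3]."""
    q = np.linspace(0.1, 3.0, 600)
    sq = osc.s_q_from_model(crystal10, q)
    ff = osc.solution_form_factor(osc.SubunitModel.sphere(1.5), q)
    return osc.ScatteringCurve(q, crystal10.n * ff.I * sq.S)
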