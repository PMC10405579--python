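"""Programmatic structural fixtures: crystals, a graphene sheet, point helices
and an ideal gas. Everything is generated in memory — no downloads, no data files.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .pointsets import LatticeSpec, PointSet, build_crystal

__all__ = [
    "FixtureSpec", "make_fixture", "cubic_crystal", "triclinic_crystal",
    "graphene_sheet", "point_helix", "ideal_gas", "GRAPHENE_A",
]

#: graphene lattice constant in nm
GRAPHENE_A = 0.246


@dataclass
class FixtureSpec:
    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0


def cubic_crystal(a: float = 3.5, repeats: tuple[int, int, int] = (10, 10, 10)) -> PointSet:
    """Simple cubic lattice, centered, with the periodic box attached."""
    spec = LatticeSpec("constants", repeats, constants=(a, a, a, 90.0, 90.0, 90.0))
    return build_crystal(spec)


def triclinic_crystal(a: float, b: float, c: float, alpha: float, beta: float,
                      gamma: float, repeats: tuple[int, int, int]) -> PointSet:
    spec = LatticeSpec("constants", repeats, constants=(a, b, c, alpha, beta, gamma))
    return build_crystal(spec)


def graphene_sheet(n1: int = 25, n3: int = 25, a: float = GRAPHENE_A) -> PointSet:
    """Honeycomb sheet in the xz plane (beam along y), two-atom basis.

    In-plane primitive vectors a1 = a (1, 0, 0) and a3 = a (1/2, 0, sqrt(3)/2);
    basis atoms at 0 and (a1 + a3) / 3. The innermost reciprocal-lattice ring
    sits at |q| = 4 pi / (a sqrt(3)).
    """
    if n1 < 1 or n3 < 1 or a <= 0:
        raise ValidationError("invalid graphene parameters")
    a1 = np.array([a, 0.0, 0.0])
    a3 = np.array([0.5 * a, 0.0, 0.5 * np.sqrt(3.0) * a])
    basis = np.array([np.zeros(3), (a1 + a3) / 3.0])
    i, j = np.meshgrid(np.arange(n1), np.arange(n3), indexing="ij")
    cells = i.ravel()[:, None] * a1 + j.ravel()[:, None] * a3
    pos = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3)
    pos -= pos.mean(axis=0)
    return PointSet(pos)


def point_helix(radius: float = 1.0, rise: float = 0.34, twist: float = 36.0,
                n_points: int = 10, n_strands: int = 1) -> PointSet:
    """Point scatterers on a helix with axis along z.

    ``rise`` is the axial step per point (nm) and ``twist`` the azimuthal step
    per point (degrees). ``n_strands = 2`` adds a second strand offset by 180
    degrees (a double helix). The set is centered axially.
    """
    if radius <= 0 or rise <= 0 or n_points < 1 or n_strands not in (1, 2):
        raise ValidationError("invalid helix parameters")
    k = np.arange(n_points)
    phi = np.radians(twist) * k
    z = rise * k
    strands = []
    offsets = [0.0] if n_strands == 1 else [0.0, np.pi]
    for off in offsets:
        strands.append(np.stack([radius * np.cos(phi + off),
                                 radius * np.sin(phi + off), z], axis=1))
    pos = np.concatenate(strands)
    pos[:, 2] -= pos[:, 2].mean()
    return PointSet(pos)


def ideal_gas(n: int = 10_000, box: tuple[float, float, float] = (50.0, 50.0, 50.0),
              seed: int = 0) -> PointSet:
    """Uncorrelated uniform points in a periodic box: g(r) = 1 up to noise."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    box_arr = np.asarray(box, dtype=float)
    if np.any(box_arr <= 0):
        raise ValidationError("box edges must be positive")
    rng = np.random.default_rng(seed)
    pos = rng.random((n, 3)) * box_arr
    return PointSet(pos, box=box_arr)


_KINDS = {
    "cubic_crystal": cubic_crystal,
    "triclinic_crystal": triclinic_crystal,
    "graphene_sheet": graphene_sheet,
    "point_helix": point_helix,
    "ideal_gas": ideal_gas,
}


def make_fixture(spec: FixtureSpec) -> PointSet:
    """Build the fixture named by ``spec.kind`` with ``spec.params``."""
    if spec.kind not in _KINDS:
        raise ValidationError(f"unknown fixture kind: {spec.kind}")
    params = dict(spec.params)
    if spec.kind == "ideal_gas":
        params.setdefault("seed", spec.seed)
    return _KINDS[spec.kind](**params)
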