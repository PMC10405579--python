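"""Point ensembles (docking lists): lattice construction, thermal fluctuations,
and Metropolis Monte Carlo equilibration.

A :class:`PointSet` is the universal structural model of this package — an ordered
list of subunit positions in nm, optionally carrying per-subunit Tait–Bryan
orientations (degrees) and a periodic box for minimum-image distances.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError

__all__ = [
    "LatticeSpec",
    "PointSet",
    "FluctuationSpec",
    "MCConfig",
    "build_crystal",
    "thermalize",
    "mc_simulate",
]


@dataclass
class PointSet:
    """Ordered subunit positions (nm) with optional orientations and periodic box."""

    positions: np.ndarray
    orientations: np.ndarray | None = None
    box: np.ndarray | None = None

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] == 0:
            raise ValidationError("positions must be a non-empty (N, 3) array")
        if not np.all(np.isfinite(pos)):
            raise ValidationError("positions must be finite")
        self.positions = pos
        if self.orientations is not None:
            ori = np.atleast_2d(np.asarray(self.orientations, dtype=float))
            if ori.shape != pos.shape:
                raise ValidationError("orientations must match positions in length")
            if not np.all(np.isfinite(ori)):
                raise ValidationError("orientations must be finite")
            self.orientations = ori
        if self.box is not None:
            box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(box <= 0) or not np.all(np.isfinite(box)):
                raise ValidationError("box edges must be positive and finite")
            self.box = box

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "PointSet":
        return PointSet(
            self.positions.copy(),
            None if self.orientations is None else self.orientations.copy(),
            None if self.box is None else self.box.copy(),
        )


@dataclass
class LatticeSpec:
    """Lattice defined either by three vectors (nm) or by constants a, b, c (nm) and
    angles alpha, beta, gamma (degrees), plus repeat counts along each axis."""

    mode: str
    repeats: tuple[int, int, int]
    vectors: np.ndarray | None = None
    constants: tuple[float, float, float, float, float, float] | None = None

    def __post_init__(self):
        if self.mode not in ("vectors", "constants"):
            raise ValidationError("mode must be 'vectors' or 'constants'")
        reps = tuple(int(r) for r in self.repeats)
        if len(reps) != 3 or any(r < 1 for r in reps):
            raise ValidationError("repeats must be three integers >= 1")
        self.repeats = reps
        if self.mode == "vectors":
            if self.vectors is None:
                raise ValidationError("mode='vectors' requires vectors")
            vec = np.asarray(self.vectors, dtype=float).reshape(3, 3)
            if not np.all(np.isfinite(vec)):
                raise ValidationError("lattice vectors must be finite")
            self.vectors = vec
        else:
            if self.constants is None:
                raise ValidationError("mode='constants' requires constants")
            a, b, c, al, be, ga = (float(x) for x in self.constants)
            if min(a, b, c) <= 0:
                raise ValidationError("lattice constants must be positive")
            for ang in (al, be, ga):
                if not 0.0 < ang < 180.0:
                    raise ValidationError("lattice angles must lie in (0, 180) degrees")
            self.constants = (a, b, c, al, be, ga)

    def lattice_vectors(self) -> np.ndarray:
        """Return the three lattice vectors as rows of a (3, 3) array."""
        if self.mode == "vectors":
            vec = self.vectors
        else:
            vec = _vectors_from_constants(*self.constants)
        vol = abs(np.linalg.det(vec))
        scale = np.prod(np.linalg.norm(vec, axis=1))
        if vol < 1e-10 * scale:
            raise ValidationError("degenerate (coplanar) lattice vectors")
        return vec


def _vectors_from_constants(a, b, c, alpha, beta, gamma) -> np.ndarray:
    # standard crystallographic frame: a along x, b in the xy-plane
    al, be, ga = (math.radians(x) for x in (alpha, beta, gamma))
    va = np.array([a, 0.0, 0.0])
    vb = np.array([b * math.cos(ga), b * math.sin(ga), 0.0])
    cx = c * math.cos(be)
    cy = c * (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)
    cz_sq = c * c - cx * cx - cy * cy
    if cz_sq <= 0:
        raise ValidationError("lattice angles do not define a 3D cell")
    vc = np.array([cx, cy, math.sqrt(cz_sq)])
    return np.vstack([va, vb, vc])


@dataclass
class FluctuationSpec:
    """Random per-coordinate displacements.

    ``uniform``: each coordinate is displaced by 2*u*v - u with v ~ U[0, 1), so the
    displacement lies in [-u, u). ``gaussian``: zero-mean normal with std sigma_u.
    """

    kind: str = "uniform"
    u: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sigma_u: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("uniform", "gaussian"):
            raise ValidationError("kind must be 'uniform' or 'gaussian'")
        u = np.asarray(self.u, dtype=float).reshape(3)
        if np.any(u < 0):
            raise ValidationError("u components must be >= 0")
        self.u = tuple(u)
        if self.sigma_u < 0:
            raise ValidationError("sigma_u must be >= 0")


@dataclass
class MCConfig:
    """Metropolis Monte Carlo configuration.

    Energies are in arbitrary but consistent units: kBT is the thermal energy in the
    same units as the potential. ``neighbor_cutoff`` selects each point's static
    nearest-neighbor set once, from the initial configuration.
    """

    potential: str = "harmonic"
    k_spring: float = 1.0
    r0_spring: float = 1.0
    epsilon: float = 1.0
    sigma_lj: float = 1.0
    kBT: float = 1.0
    max_iterations: int = 1000
    max_step: float = 0.1
    neighbor_cutoff: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.potential not in ("harmonic", "lennard_jones"):
            raise ValidationError("potential must be 'harmonic' or 'lennard_jones'")
        for name in ("k_spring", "r0_spring", "epsilon", "sigma_lj", "kBT",
                     "max_step", "neighbor_cutoff"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.max_iterations < 0:
            raise ValidationError("max_iterations must be >= 0")


def build_crystal(spec: LatticeSpec) -> PointSet:
    """Build a crystal docking list from a lattice specification.

    Points sit at integer combinations i*a + j*b + k*c, i in [0, n_a) etc., and the
    whole set is translated so its geometric center (mean position) is at the origin.
    For mutually orthogonal lattice vectors the periodic box (n_a|a|, n_b|b|, n_c|c|)
    is attached.
    """
    vec = spec.lattice_vectors()
    na, nb, nc = spec.repeats
    i, j, k = np.meshgrid(np.arange(na), np.arange(nb), np.arange(nc), indexing="ij")
    ijk = np.stack([i.ravel(), j.ravel(), k.ravel()], axis=1).astype(float)
    pos = ijk @ vec
    pos -= pos.mean(axis=0)
    box = None
    dots = np.abs(vec @ vec.T - np.diag(np.sum(vec * vec, axis=1)))
    if np.all(dots < 1e-9 * np.max(np.sum(vec * vec, axis=1))):
        box = np.array([na, nb, nc], dtype=float) * np.linalg.norm(vec, axis=1)
    return PointSet(pos, box=box)


def thermalize(points: PointSet, spec: FluctuationSpec) -> PointSet:
    """Add random displacements to each point; returns a new PointSet.

    Reproducible under a fixed spec.seed; the input is left unchanged.
    """
    rng = np.random.default_rng(spec.seed)
    out = points.copy()
    n = points.n
    if spec.kind == "uniform":
        u = np.asarray(spec.u, dtype=float)
        v = rng.random((n, 3))
        out.positions = out.positions + (2.0 * u * v - u)
    else:
        if spec.sigma_u > 0:
            out.positions = out.positions + rng.normal(0.0, spec.sigma_u, (n, 3))
    return out


def _pair_potential(r: np.ndarray, cfg: MCConfig) -> np.ndarray:
    if cfg.potential == "harmonic":
        d = r - cfg.r0_spring
        return 0.5 * cfg.k_spring * d * d
    s = cfg.sigma_lj / r
    s6 = s ** 6
    return 4.0 * cfg.epsilon * (s6 * s6 - s6)


def _neighbor_lists(points: PointSet, cutoff: float) -> list[np.ndarray]:
    pos = points.positions
    if points.box is not None:
        box = points.box
        tree = cKDTree(np.mod(pos, box), boxsize=box)
        raw = tree.query_ball_point(np.mod(pos, box), cutoff)
    else:
        tree = cKDTree(pos)
        raw = tree.query_ball_point(pos, cutoff)
    out = []
    for i, nb in enumerate(raw):
        nb = np.array([j for j in nb if j != i], dtype=int)
        if nb.size == 0:
            raise ValidationError(
                f"point {i} has no neighbors within neighbor_cutoff; "
                "increase the cutoff"
            )
        out.append(nb)
    return out


def _min_image(dvec: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is not None:
        dvec = dvec - box * np.round(dvec / box)
    return dvec


def mc_simulate(points: PointSet, config: MCConfig) -> PointSet:
    """Metropolis Monte Carlo against a pairwise potential between static nearest
    neighbors.

    Each iteration picks one random point, proposes a displacement with each
    component uniform in [-max_step, max_step), and accepts with probability
    min(1, exp(-dE/kBT)). The pairwise cost carries a factor 1/2 per interaction
    (each bond is shared between the interacting pair). Minimum-image distances
    and coordinate wrapping apply when a periodic box is present.
    """
    if points.n < 2:
        raise ValidationError("mc_simulate needs at least two points")
    neighbors = _neighbor_lists(points, config.neighbor_cutoff)
    rng = np.random.default_rng(config.seed)
    out = points.copy()
    pos = out.positions
    box = out.box
    kBT = config.kBT
    n = out.n
    for _ in range(config.max_iterations):
        i = int(rng.integers(n))
        step = config.max_step * (2.0 * rng.random(3) - 1.0)
        nb = neighbors[i]
        d_old = np.linalg.norm(_min_image(pos[nb] - pos[i], box), axis=1)
        new_ri = pos[i] + step
        if box is not None:
            new_ri = np.mod(new_ri, box)
        d_new = np.linalg.norm(_min_image(pos[nb] - new_ri, box), axis=1)
        dE = 0.5 * (_pair_potential(d_new, config).sum()
                    - _pair_potential(d_old, config).sum())
        if dE <= 0.0 or rng.random() < math.exp(-dE / kBT):
            pos[i] = new_ri
    return out


def total_energy(points: PointSet, config: MCConfig) -> float:
    """Total potential energy over the static neighbor bonds (each pair counted once)."""
    neighbors = _neighbor_lists(points, config.neighbor_cutoff)
    pos, box = points.positions, points.box
    e = 0.0
    for i, nb in enumerate(neighbors):
        d = np.linalg.norm(_min_image(pos[nb] - pos[i], box), axis=1)
        e += _pair_potential(d, config).sum()
    return 0.5 * e
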