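"""Reciprocal-space amplitude grids and hierarchical assembly.

Complex scattering amplitudes F(q, theta_q, phi_q) are sampled on polar
reciprocal-space grids: uniform radial shells up to q_max, with per-shell angular
sampling that grows with the shell index so the angular density stays roughly
uniform. Amplitudes of assemblies are sums of rotated/translated subunit
amplitudes,

    F(q) = sum_j sum_m sum_k F_j(A_jm^-1 q) exp(i q . R_jmk),

where A_jm are Tait-Bryan rotation matrices (intrinsic rotations applied in the
order alpha about x, then beta about y, then gamma about z) and R_jmk are
real-space translations. Child grids inside an assembly are evaluated by local
interpolation; closed-form leaves are evaluated exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.spatial.transform import Rotation

from .curves import ScatteringCurve
from .errors import GridRangeError, ValidationError
from .formfactors import SubunitModel, amplitude as _subunit_amplitude
from .pointsets import PointSet

__all__ = [
    "ReciprocalGrid",
    "Placement",
    "AssemblyNode",
    "rotation_matrix",
    "fill_grid",
    "assemble_amplitude",
    "evaluate_amplitude",
    "multiply_grids",
    "sum_grids",
    "orientation_average",
]


def rotation_matrix(angles_deg) -> np.ndarray:
    """Tait-Bryan rotation matrix: intrinsic x (alpha), then y (beta), then z (gamma)."""
    a, b, g = (float(x) for x in angles_deg)
    return Rotation.from_euler("XYZ", [a, b, g], degrees=True).as_matrix()


@dataclass
class Placement:
    """One copy of a subunit: a Tait-Bryan rotation (degrees) plus a translation (nm)."""

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        return rotation_matrix(self.rotation)


@dataclass
class AssemblyNode:
    """A node of the hierarchical model tree.

    ``children`` is a list of (source, placements) pairs, where source is a
    SubunitModel, a PointSet of unit point scatterers, a ReciprocalGrid, or a
    nested AssemblyNode, and placements is a non-empty list of
    :class:`Placement` copies of that source.
    """

    children: list = field(default_factory=list)

    def __post_init__(self):
        if not self.children:
            raise ValidationError("assembly node needs at least one child")
        for src, placements in self.children:
            if not placements:
                raise ValidationError("every child needs at least one placement")


AmplitudeSource = Union[SubunitModel, PointSet, "ReciprocalGrid", AssemblyNode]


def _catmull_rom_weights(t: np.ndarray) -> np.ndarray:
    """Catmull-Rom cubic weights for the 4-point stencil, shape (len(t), 4)."""
    t2 = t * t
    t3 = t2 * t
    return np.stack([
        -0.5 * t + t2 - 0.5 * t3,
        1.0 - 2.5 * t2 + 1.5 * t3,
        0.5 * t + 2.0 * t2 - 1.5 * t3,
        -0.5 * t2 + 0.5 * t3,
    ], axis=-1)


class ReciprocalGrid:
    """Complex amplitudes on a polar reciprocal-space grid.

    Shell ``i`` (i = 0..n_shells) sits at q = i * q_max / n_shells. Shell 0 is a
    single value at the origin. Shell i >= 1 carries 2i + 1 polar samples
    (theta uniform on [0, pi], poles included) and 2 * (2i + 1) azimuthal samples
    (phi uniform on [0, 2 pi)); values at the poles are angular-independent and
    stored replicated across phi.
    """

    def __init__(self, q_max: float, n_shells: int,
                 shells: list[np.ndarray] | None = None):
        if q_max <= 0 or n_shells < 1:
            raise ValidationError("q_max and n_shells must be positive")
        self.q_max = float(q_max)
        self.n_shells = int(n_shells)
        if shells is None:
            shells = [np.zeros(self.shell_shape(i), dtype=complex)
                      for i in range(n_shells + 1)]
        if len(shells) != n_shells + 1:
            raise ValidationError("shell count must equal n_shells + 1")
        for i, sh in enumerate(shells):
            if sh.shape != self.shell_shape(i):
                raise ValidationError(f"shell {i} has wrong shape {sh.shape}")
        self.shells = shells

    # --- layout -------------------------------------------------------------
    @property
    def dq(self) -> float:
        return self.q_max / self.n_shells

    def shell_q(self, i: int) -> float:
        return i * self.dq

    @staticmethod
    def shell_shape(i: int) -> tuple[int, int]:
        if i == 0:
            return (1, 1)
        n_theta = 2 * i + 1
        return (n_theta, 2 * n_theta)

    def shell_angles(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        n_theta, n_phi = self.shell_shape(i)
        theta = np.linspace(0.0, np.pi, n_theta) if i > 0 else np.zeros(1)
        phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
        return theta, phi

    def shell_qvecs(self, i: int) -> np.ndarray:
        """All (theta, phi) nodes of shell i as Cartesian q-vectors, shape (nt, np, 3)."""
        theta, phi = self.shell_angles(i)
        q = self.shell_q(i)
        st, ct = np.sin(theta)[:, None], np.cos(theta)[:, None]
        return q * np.stack([st * np.cos(phi)[None, :],
                             st * np.sin(phi)[None, :],
                             np.broadcast_to(ct, (theta.size, phi.size))], axis=-1)

    def same_layout(self, other: "ReciprocalGrid") -> bool:
        return (abs(self.q_max - other.q_max) < 1e-12 * self.q_max
                and self.n_shells == other.n_shells)

    def copy(self) -> "ReciprocalGrid":
        return ReciprocalGrid(self.q_max, self.n_shells,
                              [s.copy() for s in self.shells])

    # --- interpolation ------------------------------------------------------
    def _shell_eval(self, i: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """Interpolated amplitude on shell i at (theta, phi); exact at shell nodes.

        Bicubic Catmull-Rom with periodic phi, falling back to bilinear where the
        theta stencil would cross a pole.
        """
        v = self.shells[i]
        if i == 0:
            return np.full(theta.shape, v[0, 0], dtype=complex)
        n_theta, n_phi = v.shape
        d_theta = np.pi / (n_theta - 1)
        d_phi = 2.0 * np.pi / n_phi
        u = np.mod(phi, 2.0 * np.pi) / d_phi
        j0 = np.floor(u + 1e-12).astype(int)
        fu = u - j0
        j0 = np.mod(j0, n_phi)
        t = np.clip(theta, 0.0, np.pi) / d_theta
        r0 = np.clip(np.floor(t + 1e-12).astype(int), 0, n_theta - 2)
        ft = t - r0
        out = np.empty(theta.shape, dtype=complex)
        cubic = (r0 >= 1) & (r0 <= n_theta - 3)
        if np.any(cubic):
            jc = j0[cubic]
            wphi = _catmull_rom_weights(fu[cubic])
            rows = []
            for dr_ in (-1, 0, 1, 2):
                rr = r0[cubic] + dr_
                acc = 0.0
                for dp in range(4):
                    cols = np.mod(jc + dp - 1, n_phi)
                    acc = acc + wphi[:, dp] * v[rr, cols]
                rows.append(acc)
            wth = _catmull_rom_weights(ft[cubic])
            out[cubic] = sum(wth[:, k] * rows[k] for k in range(4))
        lin = ~cubic
        if np.any(lin):
            jl = j0[lin]
            jl1 = np.mod(jl + 1, n_phi)
            fl = fu[lin]
            rl = r0[lin]
            row_a = (1.0 - fl) * v[rl, jl] + fl * v[rl, jl1]
            row_b = (1.0 - fl) * v[rl + 1, jl] + fl * v[rl + 1, jl1]
            out[lin] = (1.0 - ft[lin]) * row_a + ft[lin] * row_b
        return out

    def interpolate(self, qvec) -> np.ndarray:
        """Amplitude at arbitrary q-vector(s) with |q| <= q_max.

        Separable local interpolation: bicubic on each angular shell, then a
        Catmull-Rom cubic across the four surrounding radial shells (linear near
        q = 0 and q_max). Exact at grid nodes.
        """
        qv = np.asarray(qvec, dtype=float)
        scalar = qv.ndim == 1
        out_shape = np.atleast_2d(qv).shape[:-1]
        qv = np.atleast_2d(qv).reshape(-1, 3)
        q = np.linalg.norm(qv, axis=-1)
        if np.any(q > self.q_max * (1.0 + 1e-9)):
            raise GridRangeError(
                f"|q| = {q.max():.6g} exceeds the grid q_max = {self.q_max:.6g}"
            )
        with np.errstate(invalid="ignore"):
            ct = np.where(q > 0, qv[..., 2] / np.maximum(q, 1e-300), 1.0)
        theta = np.arccos(np.clip(ct, -1.0, 1.0))
        phi = np.mod(np.arctan2(qv[..., 1], qv[..., 0]), 2.0 * np.pi)
        t = q / self.dq
        i0 = np.clip(np.floor(t + 1e-12).astype(int), 0, self.n_shells - 1)
        fq = t - i0
        cubic = (i0 >= 1) & (i0 <= self.n_shells - 2)
        idx = np.empty((q.size, 4), dtype=int)
        w = np.empty((q.size, 4), dtype=float)
        if np.any(cubic):
            w[cubic] = _catmull_rom_weights(fq[cubic])
            idx[cubic] = i0[cubic, None] + np.array([-1, 0, 1, 2])
        lin = ~cubic
        if np.any(lin):
            idx[lin, 0] = i0[lin]
            idx[lin, 1] = np.minimum(i0[lin] + 1, self.n_shells)
            idx[lin, 2] = 0
            idx[lin, 3] = 0
            w[lin, 0] = 1.0 - fq[lin]
            w[lin, 1] = fq[lin]
            w[lin, 2] = 0.0
            w[lin, 3] = 0.0
        out = np.zeros(q.size, dtype=complex)
        for s in np.unique(idx[w != 0.0] if np.any(w != 0.0) else idx):
            for pos in range(4):
                sel = (idx[:, pos] == s) & (w[:, pos] != 0.0)
                if not np.any(sel):
                    continue
                out[sel] += w[sel, pos] * self._shell_eval(int(s), theta[sel], phi[sel])
        return out[0] if scalar else out.reshape(out_shape)


def _pointset_amplitude(points: PointSet, qvecs: np.ndarray) -> np.ndarray:
    """Coherent sum of unit point scatterers: sum_i exp(i q . r_i)."""
    pos = points.positions
    out = np.zeros(qvecs.shape[0], dtype=complex)
    chunk = max(1, int(4e6) // max(1, pos.shape[0]))
    for s in range(0, qvecs.shape[0], chunk):
        out[s:s + chunk] = np.exp(1j * qvecs[s:s + chunk] @ pos.T).sum(axis=1)
    return out


def evaluate_amplitude(source: AmplitudeSource, qvecs) -> np.ndarray:
    """Complex amplitude of any source at (M, 3) q-vectors (nm^-1)."""
    qv = np.atleast_2d(np.asarray(qvecs, dtype=float))
    if isinstance(source, SubunitModel):
        return _subunit_amplitude(source, qv)
    if isinstance(source, PointSet):
        return _pointset_amplitude(source, qv)
    if isinstance(source, ReciprocalGrid):
        return source.interpolate(qv)
    if isinstance(source, AssemblyNode):
        out = np.zeros(qv.shape[0], dtype=complex)
        for child, placements in source.children:
            for pl in placements:
                a = pl.matrix()
                child_amp = evaluate_amplitude(child, qv @ a)
                tvec = np.asarray(pl.translation, dtype=float)
                out += child_amp * np.exp(1j * (qv @ tvec))
        return out
    raise ValidationError(f"unsupported amplitude source: {type(source).__name__}")


def assemble_amplitude(spec: AssemblyNode, qvec) -> np.ndarray:
    """Amplitude of a hierarchical assembly at one or many q-vectors."""
    qv = np.asarray(qvec, dtype=float)
    scalar = qv.ndim == 1
    out = evaluate_amplitude(spec, np.atleast_2d(qv))
    return out[0] if scalar else out


def fill_grid(source: AmplitudeSource, q_max: float, n_shells: int) -> ReciprocalGrid:
    """Evaluate a source amplitude at every node of a fresh polar grid."""
    grid = ReciprocalGrid(q_max, n_shells)
    for i in range(n_shells + 1):
        qv = grid.shell_qvecs(i)
        vals = evaluate_amplitude(source, qv.reshape(-1, 3))
        grid.shells[i] = vals.reshape(qv.shape[:-1])
    return grid


def _check_layout(a: ReciprocalGrid, b: ReciprocalGrid) -> None:
    if not a.same_layout(b):
        raise ValidationError("grids must share q_max and n_shells")


def multiply_grids(a: ReciprocalGrid, b: ReciprocalGrid) -> ReciprocalGrid:
    """Node-wise complex product of two grids with identical layouts."""
    _check_layout(a, b)
    return ReciprocalGrid(a.q_max, a.n_shells,
                          [x * y for x, y in zip(a.shells, b.shells)])


def sum_grids(a: ReciprocalGrid, b: ReciprocalGrid) -> ReciprocalGrid:
    """Node-wise complex sum of two grids with identical layouts."""
    _check_layout(a, b)
    return ReciprocalGrid(a.q_max, a.n_shells,
                          [x + y for x, y in zip(a.shells, b.shells)])


def _uniform_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    """Area-preserving solid-angle sampling: phi = 2 pi u, cos(theta) = 2v - 1."""
    u = rng.random(n)
    v = rng.random(n)
    phi = 2.0 * np.pi * u
    ct = 2.0 * v - 1.0
    st = np.sqrt(1.0 - ct * ct)
    return np.stack([st * np.cos(phi), st * np.sin(phi), ct], axis=1)


def orientation_average(source: AmplitudeSource, q_grid, rel_tol: float = 1e-3,
                        max_samples: int = 2 ** 16, seed: int = 0) -> ScatteringCurve:
    """Monte Carlo orientation average of the intensity, I(q) = <|F(q)|^2>_Omega.

    The solid-angle sample budget doubles until the relative L2 change of the
    whole curve between consecutive cumulative estimates drops below ``rel_tol``
    or ``max_samples`` is reached (in which case the curve is flagged
    unconverged in its metadata rather than raising).
    """
    if rel_tol <= 0:
        raise ValidationError("rel_tol must be positive")
    q = np.asarray(q_grid, dtype=float)
    rng = np.random.default_rng(seed)
    total = np.zeros(q.size)
    count = 0
    batch = 128
    prev = None
    converged = False
    while count < max_samples:
        m = min(batch, max_samples - count)
        dirs = _uniform_directions(rng, m)
        # evaluate in chunks of directions to bound the (nq * m, 3) workspace
        step = max(1, int(2e6) // max(1, q.size))
        for s in range(0, m, step):
            d = dirs[s:s + step]
            qv = (q[:, None, None] * d[None, :, :]).reshape(-1, 3)
            amp = evaluate_amplitude(source, qv).reshape(q.size, -1)
            total += (amp.real ** 2 + amp.imag ** 2).sum(axis=1)
        count += m
        cur = total / count
        if prev is not None:
            denom = np.linalg.norm(cur)
            change = np.linalg.norm(cur - prev) / denom if denom > 0 else 0.0
            if change < rel_tol:
                converged = True
                break
        prev = cur.copy()
        batch *= 2
    return ScatteringCurve(q, total / count, metadata={
        "converged": converged, "n_samples": count, "seed": seed,
        "rel_tol": rel_tol,
    })
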