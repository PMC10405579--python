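"""1D curve containers: scattering intensity, structure factor, radial distribution.

All reciprocal-space axes are in nm^-1, all real-space axes in nm. Intensities are in
electron units (the Thomson-length squared prefactor is a constant multiplicative scale
and is deliberately left out; see the methods note).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError(f"{name} must be a non-empty 1D array")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def _check_q_grid(q: np.ndarray) -> None:
    if np.any(q < 0):
        raise ValidationError("q grid must be non-negative")
    if np.any(np.diff(q) <= 0):
        raise ValidationError("q grid must be strictly ascending")


@dataclass
class ScatteringCurve:
    """Scattering intensity I(q) on an ascending q grid."""

    q: np.ndarray
    I: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = _as_1d(self.q, "q")
        self.I = _as_1d(self.I, "I")
        _check_q_grid(self.q)
        if self.q.shape != self.I.shape:
            raise ValidationError("q and I must have equal length")


@dataclass
class StructureFactorCurve:
    """Orientation-averaged structure factor S(q) for a model of N subunits.

    Normalised so that S(0) = N and S(q) -> 1 at large q.
    """

    q: np.ndarray
    S: np.ndarray
    n_subunits: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = _as_1d(self.q, "q")
        self.S = _as_1d(self.S, "S")
        _check_q_grid(self.q)
        if self.q.shape != self.S.shape:
            raise ValidationError("q and S must have equal length")
        if self.n_subunits < 1:
            raise ValidationError("n_subunits must be a positive integer")
        self.n_subunits = int(self.n_subunits)


@dataclass
class RDFCurve:
    """Radial distribution function g(r) on uniform bins of width dr.

    ``r`` holds bin centers. ``rho_b`` is the bulk subunit number density in nm^-3.
    g(r) obtained by direct binning is non-negative; g(r) obtained from a truncated
    sine transform may oscillate below zero near truncation artifacts.
    """

    r: np.ndarray
    g: np.ndarray
    rho_b: float
    dr: float
    r_max: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.r = _as_1d(self.r, "r")
        self.g = _as_1d(self.g, "g")
        if self.r.shape != self.g.shape:
            raise ValidationError("r and g must have equal length")
        if np.any(self.r <= 0):
            raise ValidationError("r grid must be strictly positive")
        if self.rho_b <= 0:
            raise ValidationError("rho_b must be positive")
        if self.dr <= 0:
            raise ValidationError("dr must be positive")
        steps = np.diff(self.r)
        if steps.size and not np.allclose(steps, self.dr, rtol=1e-6, atol=1e-12):
            raise ValidationError("r grid must be uniform with spacing dr")
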