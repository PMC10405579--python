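"""2D scattering patterns: single-orientation Ewald-plane slices and fiber
diffraction (azimuthal Monte Carlo averages).

The detector plane is identified with the (q_perp, q_z) plane (flat-detector
small-angle approximation, no Ewald-sphere curvature). Each pixel is converted
to polar reciprocal coordinates q = (q_perp^2 + q_z^2)^(1/2),
theta_q = arccos(q_z / q); a single-orientation image samples the amplitude at
azimuth phi' for q_perp >= 0 and phi' + pi for q_perp < 0, while a fiber image
averages |F|^2 over a uniform azimuth distribution.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .recgrid import AmplitudeSource, ReciprocalGrid, evaluate_amplitude

__all__ = ["DetectorImage", "single_orientation_pattern", "fiber_pattern"]


@dataclass
class DetectorImage:
    """Square intensity matrix over (q_perp, q_z) with pixel-to-q metadata.

    ``values[i, j]`` is the intensity at q_z = q_z_axis[i], q_perp =
    q_perp_axis[j]; both axes run from -q_limit to q_limit through pixel
    centers. ``mask`` flags pixels beyond the source's q_max (zero-filled).
    """

    values: np.ndarray
    q_perp_axis: np.ndarray
    q_z_axis: np.ndarray
    q_limit: float
    phi_prime: float = 0.0
    mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("values must be a square matrix")
        if np.any(~np.isfinite(v)) or np.any(v < 0):
            raise ValidationError("intensities must be finite and non-negative")
        self.values = v

    @property
    def n_points(self) -> int:
        return self.values.shape[0]


def _pixel_axes(n_points: int, q_limit: float) -> np.ndarray:
    """Pixel-center coordinates; even n_points keeps q = 0 off the grid."""
    if n_points <= 0 or n_points % 2:
        raise ValidationError("n_points must be a positive even integer")
    if q_limit <= 0:
        raise ValidationError("q_limit must be positive")
    step = 2.0 * q_limit / n_points
    return (np.arange(n_points) + 0.5) * step - q_limit


def _polar_pixels(n_points: int, q_limit: float):
    ax = _pixel_axes(n_points, q_limit)
    q_perp, q_z = np.meshgrid(ax, ax)  # rows: q_z, cols: q_perp
    q = np.hypot(q_perp, q_z)
    theta = np.arccos(np.clip(np.where(q > 0, q_z / np.maximum(q, 1e-300), 1.0),
                              -1.0, 1.0))
    return ax, q_perp, q_z, q, theta


def single_orientation_pattern(grid: ReciprocalGrid, n_points: int, q_limit: float,
                               phi_prime: float = 0.0) -> DetectorImage:
    """2D intensity of a structure in a single orientation (beam along y).

    ``phi_prime`` (degrees) selects the sampled azimuthal plane; negative
    q_perp pixels sample phi' + 180 degrees. Pixels with q beyond the grid's
    q_max are zero-filled and flagged in the mask.
    """
    if q_limit > grid.q_max * (1 + 1e-9):
        raise ValidationError("q_limit must not exceed the grid q_max")
    ax, q_perp, q_z, q, theta = _polar_pixels(n_points, q_limit)
    phi0 = np.radians(phi_prime)
    phi = np.where(q_perp >= 0, phi0, phi0 + np.pi)
    mask = q > grid.q_max
    st = np.sin(theta)
    qv = np.stack([q * st * np.cos(phi), q * st * np.sin(phi), q * np.cos(theta)],
                  axis=-1)
    vals = np.zeros_like(q)
    ok = ~mask
    amp = grid.interpolate(qv[ok])
    vals[ok] = amp.real ** 2 + amp.imag ** 2
    return DetectorImage(vals, ax.copy(), ax.copy(), q_limit, phi_prime, mask,
                         metadata={"mode": "single_orientation"})


def fiber_pattern(source: AmplitudeSource, n_points: int, q_limit: float,
                  phi_domain: tuple[float, float] = (0.0, 360.0),
                  rel_tol: float = 1e-3, max_samples: int = 2 ** 12,
                  seed: int = 0) -> DetectorImage:
    """Fiber diffraction image: per pixel, the Monte Carlo average of
    |F(q, theta_q, phi)|^2 with phi uniform on ``phi_domain`` (degrees).

    The azimuth budget doubles until the image-wide relative change between
    consecutive cumulative estimates is below ``rel_tol`` or ``max_samples``
    is reached (flagged unconverged in the metadata, not an error).
    """
    lo, hi = (float(x) for x in phi_domain)
    if not lo < hi <= lo + 360.0:
        raise ValidationError("require phi_min < phi_max <= phi_min + 360")
    ax, q_perp, q_z, q, theta = _polar_pixels(n_points, q_limit)
    q_max = source.q_max if isinstance(source, ReciprocalGrid) else None
    mask = q > q_max if q_max is not None else np.zeros_like(q, dtype=bool)
    ok = ~mask
    qo, to = q[ok], theta[ok]
    st, ct = np.sin(to), np.cos(to)
    # detector convention: negative q_perp pixels sample phi + pi
    sgn = np.where(q_perp[ok] >= 0, 1.0, -1.0)
    rng = np.random.default_rng(seed)
    total = np.zeros(qo.size)
    count = 0
    batch = 8
    prev = None
    converged = False
    lo_r, hi_r = np.radians(lo), np.radians(hi)
    while count < max_samples:
        m = min(batch, max_samples - count)
        phis = lo_r + (hi_r - lo_r) * rng.random(m)
        for ph in phis:
            qv = np.stack([sgn * qo * st * np.cos(ph), sgn * qo * st * np.sin(ph),
                           qo * ct], axis=-1)
            amp = evaluate_amplitude(source, qv)
            total += amp.real ** 2 + amp.imag ** 2
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
    vals = np.zeros_like(q)
    vals[ok] = total / count
    return DetectorImage(vals, ax.copy(), ax.copy(), q_limit, float("nan"), mask,
                         metadata={"mode": "fiber", "phi_domain": (lo, hi),
                                   "converged": converged, "n_samples": count,
                                   "seed": seed})
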