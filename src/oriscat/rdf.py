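"""Radial distribution functions from point models and from structure factors,
and the coordination-number integral.

g(r) from a model is computed by shell binning around reference subunits:
g(r) = N(r) / (4 pi r^2 dr rho_b), with N(r) the mean number of subunits in the
shell [r, r + dr) and rho_b = N / V the bulk number density from the periodic box.
"""
from __future__ import annotations

import numpy as np
from scipy.fft import dst
from scipy.integrate import simpson

from .curves import RDFCurve, StructureFactorCurve
from .errors import ValidationError
from .pointsets import FluctuationSpec, PointSet, thermalize

__all__ = ["g_r_from_model", "g_r_from_s_q", "coordination_number"]


def _min_image_distances(ref: np.ndarray, pos: np.ndarray, box: np.ndarray) -> np.ndarray:
    d = pos[None, :, :] - ref[:, None, :]
    d -= box * np.round(d / box)
    return np.sqrt((d * d).sum(axis=-1))


def _sphere_shell_fraction(d: np.ndarray, edge: float, radius: float) -> np.ndarray:
    """Fraction of a sphere of ``radius`` centered at distance d (from the origin)
    whose volume lies inside the ball of radius ``edge`` about the origin."""
    out = np.zeros_like(d)
    if edge <= 0:
        return out
    full = edge >= d + radius
    out[full] = 1.0
    ball_inside = (~full) & (radius >= d + edge)
    out[ball_inside] = (edge / radius) ** 3
    lens = (~full) & (~ball_inside) & (d < edge + radius)
    dl = d[lens]
    r1, r2 = edge, radius
    v = (np.pi * (r1 + r2 - dl) ** 2
         * (dl * dl + 2 * dl * r1 - 3 * r1 * r1 + 2 * dl * r2 + 6 * r1 * r2 - 3 * r2 * r2)
         / (12.0 * dl))
    out[lens] = v / (4.0 / 3.0 * np.pi * radius ** 3)
    return out


def g_r_from_model(points: PointSet, dr: float, r_max: float,
                   subunit_radius: float = 0.0, n_configs: int = 1,
                   n_refs: int | None = None,
                   fluct: FluctuationSpec | None = None,
                   seed: int | None = None) -> RDFCurve:
    """Radial distribution function of a point model by shell binning.

    Distances use the minimum-image convention under the periodic box (required:
    it defines rho_b = N/V). With ``subunit_radius > 0`` each neighbor deposits
    into every bin the exact fraction of its spherical volume lying in that
    shell, instead of a point count. References default to all subunits
    (deterministic); ``n_refs < N`` selects a random subset (seeded). With
    ``n_configs > 1`` the histogram is averaged over thermalized configurations.
    """
    if points.box is None:
        raise ValidationError("g_r_from_model requires a periodic box (rho_b = N/V)")
    box = points.box
    if dr <= 0:
        raise ValidationError("dr must be positive")
    if r_max > 0.5 * box.min() + 1e-12:
        raise ValidationError("r_max must not exceed half the smallest box edge")
    if n_configs < 1:
        raise ValidationError("n_configs must be >= 1")
    if n_configs > 1 and fluct is None:
        raise ValidationError("n_configs > 1 requires a FluctuationSpec")
    n = points.n
    rho_b = n / float(np.prod(box))
    edges = dr * np.arange(0, int(np.floor(r_max / dr + 1e-9)) + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_bins = centers.size
    rng = np.random.default_rng(seed)
    if n_configs > 1:
        cfg_seeds = np.random.SeedSequence(fluct.seed).generate_state(n_configs) % (2 ** 31)

    counts = np.zeros(n_bins)
    for c in range(n_configs):
        if fluct is not None:
            sub = FluctuationSpec(kind=fluct.kind, u=fluct.u, sigma_u=fluct.sigma_u,
                                  seed=int(cfg_seeds[c]) if n_configs > 1 else fluct.seed)
            cfg = thermalize(points, sub)
        else:
            cfg = points
        if n_refs is None or n_refs >= n:
            ref_idx = np.arange(n)
        else:
            ref_idx = rng.choice(n, size=n_refs, replace=False)
        pos = cfg.positions
        # chunk references to bound the (refs, N) distance matrix
        chunk = max(1, int(2e6) // n)
        cfg_counts = np.zeros(n_bins)
        for s in range(0, ref_idx.size, chunk):
            idx = ref_idx[s:s + chunk]
            d = _min_image_distances(pos[idx], pos, box)
            # exclude the self term
            for row, i in enumerate(idx):
                d[row, i] = np.inf
            d = d.ravel()
            d = d[np.isfinite(d)]
            if subunit_radius > 0.0:
                d = d[d <= r_max + subunit_radius]
                prev = _sphere_shell_fraction(d, edges[0], subunit_radius)
                for k in range(n_bins):
                    cur = _sphere_shell_fraction(d, edges[k + 1], subunit_radius)
                    cfg_counts[k] += (cur - prev).sum()
                    prev = cur
            else:
                h, _ = np.histogram(d, bins=edges)
                cfg_counts += h
        counts += cfg_counts / ref_idx.size
    counts /= n_configs
    g = counts / (4.0 * np.pi * centers ** 2 * dr * rho_b)
    return RDFCurve(centers, g, rho_b, dr, float(edges[-1]),
                    metadata={"subunit_radius": subunit_radius,
                              "n_configs": n_configs, "source": "model"})


def g_r_from_s_q(sq: StructureFactorCurve, rho_b: float, r_grid,
                 q_max: float, method: str = "simpson") -> RDFCurve:
    """Radial distribution function from a structure factor:

        g(r) = 1 + 1/(2 pi^2 rho_b r) * integral_0^{q_max} q [S(q) - 1] sin(qr) dq

    Truncation at q_max produces ringing: the result may oscillate below zero
    near sharp features. ``method='dst'`` resamples q [S - 1] onto a uniform
    grid n*dq and applies a type-I discrete sine transform, interpolating the
    result onto ``r_grid``.
    """
    if rho_b <= 0:
        raise ValidationError("rho_b must be positive")
    r = np.asarray(r_grid, dtype=float)
    if np.any(r <= 0):
        raise ValidationError("r = 0 must be excluded from the grid")
    steps = np.diff(r)
    if r.size < 2 or not np.allclose(steps, steps[0], rtol=1e-6):
        raise ValidationError("r_grid must be uniform with at least two points")
    dr = float(steps[0])
    mask = sq.q <= q_max + 1e-12
    q, S = sq.q[mask], sq.S[mask]
    if q.size < 3 or q[-1] < q_max - max(1e-9, q[1] - q[0]):
        raise ValidationError("structure factor must cover [0, q_max]")
    y = q * (S - 1.0)
    if method == "simpson":
        integ = np.empty_like(r)
        chunk = max(1, int(4e7) // q.size)
        for s in range(0, r.size, chunk):
            rs = r[s:s + chunk, None]
            integ[s:s + chunk] = simpson(y[None, :] * np.sin(rs * q[None, :]), x=q, axis=1)
        g = 1.0 + integ / (2.0 * np.pi ** 2 * rho_b * r)
    elif method == "dst":
        dq = float(np.median(np.diff(q)))
        m0 = int(np.floor(q[-1] / dq + 1e-9))
        qn = dq * np.arange(1, m0 + 1)
        yn = np.interp(qn, q, y)
        # zero-pad beyond the q_max truncation to refine the output r grid
        m = 8 * m0
        yp = np.zeros(m)
        yp[:m0] = yn
        X = dst(yp, type=1)
        rk = np.pi * np.arange(1, m + 1) / ((m + 1) * dq)
        gk = 1.0 + (0.5 * dq * X) / (2.0 * np.pi ** 2 * rho_b * rk)
        g = np.interp(r, rk, gk)
    else:
        raise ValidationError("method must be 'simpson' or 'dst'")
    return RDFCurve(r, g, rho_b, dr, float(r[-1] + dr / 2),
                    metadata={"method": method, "q_max": q_max, "source": "s_q"})


def coordination_number(rdf: RDFCurve, r1: float, r2: float,
                        method: str = "simpson") -> float:
    """Number of neighbors in the shell [r1, r2]:

        nn = 4 pi rho_b * integral_{r1}^{r2} r^2 g(r) dr

    ``method='simpson'`` integrates on the stored bin centers inside the window,
    augmented with linearly interpolated endpoint values at r1 and r2.
    ``method='shell_sum'`` sums 4 pi rho_b r_c^2 g dr over bins whose centers lie
    in the window — the exact inverse of the binning normalisation, so an ideal
    first shell integrates to its exact neighbor count.
    """
    if not (r1 < r2 <= rdf.r_max + 1e-12):
        raise ValidationError("require r1 < r2 <= r_max")
    if r1 < rdf.r[0] - rdf.dr / 2 - 1e-12:
        raise ValidationError("r1 below the stored grid")
    r, g = rdf.r, rdf.g
    if method == "shell_sum":
        m = (r >= r1) & (r <= r2)
        return float(4.0 * np.pi * rdf.rho_b * np.sum(r[m] ** 2 * g[m]) * rdf.dr)
    if method != "simpson":
        raise ValidationError("method must be 'simpson' or 'shell_sum'")
    integrand = 4.0 * np.pi * rdf.rho_b * r ** 2 * g
    m = (r > r1) & (r < r2)
    xs = r[m]
    ys = integrand[m]
    x1, y1 = r1, np.interp(r1, r, integrand)
    x2, y2 = r2, np.interp(r2, r, integrand)
    x = np.concatenate([[x1], xs, [x2]])
    y = np.concatenate([[y1], ys, [y2]])
    keep = np.concatenate([[True], np.diff(x) > 1e-12])
    return float(simpson(y[keep], x=x[keep]))
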