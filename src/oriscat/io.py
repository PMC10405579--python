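"""File formats: docking-list ('dol') text files, two-column curve files, and
HDF5 containers for reciprocal grids and detector images.

The dol format is plain text, whitespace-separated, one row per subunit:

    index x y z [alpha beta gamma]

with coordinates in nm, Tait-Bryan angles in degrees, and '#'-prefixed comment
lines. Curve files are two-column text (x, y) with '# key = value' headers
carrying metadata (units, seed, convergence flags, curve type).
"""
from __future__ import annotations

import ast
from pathlib import Path

import h5py
import numpy as np

from .curves import RDFCurve, ScatteringCurve, StructureFactorCurve
from .detector2d import DetectorImage
from .errors import ValidationError
from .pointsets import PointSet
from .recgrid import ReciprocalGrid

__all__ = [
    "read_dol", "write_dol", "read_curve", "write_curve",
    "write_grid", "read_grid", "write_image", "read_image",
]

_FORMAT_VERSION = 1


def write_dol(points: PointSet, path) -> None:
    """Write a docking list; the periodic box (if any) goes in a header comment."""
    lines = ["# oriscat dol v1: index x y z [alpha beta gamma]; nm, degrees"]
    if points.box is not None:
        b = points.box
        lines.append("# box = " + " ".join(repr(float(x)) for x in b))
    for i in range(points.n):
        row = f"{i}\t" + "\t".join(repr(float(x)) for x in points.positions[i])
        if points.orientations is not None:
            row += "\t" + "\t".join(repr(float(x)) for x in points.orientations[i])
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def read_dol(path) -> PointSet:
    """Read a docking list written by :func:`write_dol` (round-trip exact)."""
    pos, ori = [], []
    box = None
    has_ori = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("box"):
                try:
                    box = [float(t) for t in body.split("=", 1)[1].split()]
                except (IndexError, ValueError):
                    raise ValidationError(f"malformed box header at line {lineno}")
            continue
        tokens = line.split()
        if len(tokens) not in (4, 7):
            raise ValidationError(
                f"line {lineno}: expected 4 or 7 columns, got {len(tokens)}"
            )
        try:
            vals = [float(t) for t in tokens[1:]]
        except ValueError:
            raise ValidationError(f"line {lineno}: non-numeric coordinate")
        row_has_ori = len(tokens) == 7
        if has_ori is None:
            has_ori = row_has_ori
        elif has_ori != row_has_ori:
            raise ValidationError(f"line {lineno}: inconsistent column count")
        pos.append(vals[:3])
        if row_has_ori:
            ori.append(vals[3:])
    if not pos:
        raise ValidationError(f"{path}: no data rows")
    return PointSet(np.array(pos), np.array(ori) if ori else None,
                    np.array(box) if box is not None else None)


def _format_meta(md: dict) -> list[str]:
    out = []
    for k, v in md.items():
        if isinstance(v, np.generic):
            v = v.item()
        out.append(f"# {k} = {v!r}")
    return out


def _parse_meta(lines: list[str]) -> dict:
    md = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" not in body:
            continue
        key, _, val = body.partition("=")
        try:
            md[key.strip()] = ast.literal_eval(val.strip())
        except (ValueError, SyntaxError):
            md[key.strip()] = val.strip()
    return md


def write_curve(curve, path) -> None:
    """Write a curve as two-column text with metadata headers.

    Accepts :class:`ScatteringCurve` (type 'intensity'),
    :class:`StructureFactorCurve` ('structure_factor') and :class:`RDFCurve`
    ('rdf'); the type and the fields needed to rebuild the object go into the
    header, so :func:`read_curve` round-trips to the same class.
    """
    md = dict(getattr(curve, "metadata", {}))
    if isinstance(curve, StructureFactorCurve):
        md["curve_type"] = "structure_factor"
        md["n_subunits"] = curve.n_subunits
        x, y = curve.q, curve.S
        cols = "q[nm^-1] S"
    elif isinstance(curve, RDFCurve):
        md["curve_type"] = "rdf"
        md["rho_b"] = curve.rho_b
        md["dr"] = curve.dr
        md["r_max"] = curve.r_max
        x, y = curve.r, curve.g
        cols = "r[nm] g"
    elif isinstance(curve, ScatteringCurve):
        md["curve_type"] = "intensity"
        x, y = curve.q, curve.I
        cols = "q[nm^-1] I"
    else:
        raise ValidationError(f"cannot write object of type {type(curve).__name__}")
    lines = [f"# columns: {cols}"] + _format_meta(md)
    lines += [f"{float(xi)!r}\t{float(yi)!r}" for xi, yi in zip(x, y)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_curve(path):
    """Read a two-column curve file; returns the class named by its header."""
    header, data = [], []
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            header.append(line)
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise ValidationError(f"line {lineno}: expected two columns")
        try:
            data.append((float(tokens[0]), float(tokens[1])))
        except ValueError:
            raise ValidationError(f"line {lineno}: non-numeric value")
    if not data:
        raise ValidationError(f"{path}: no data rows")
    md = _parse_meta(header)
    arr = np.array(data)
    x, y = arr[:, 0], arr[:, 1]
    ctype = md.pop("curve_type", "intensity")
    if ctype == "structure_factor":
        n = int(md.pop("n_subunits", 1))
        return StructureFactorCurve(x, y, n, md)
    if ctype == "rdf":
        rho_b = float(md.pop("rho_b"))
        dr = float(md.pop("dr"))
        r_max = float(md.pop("r_max"))
        return RDFCurve(x, y, rho_b, dr, r_max, md)
    return ScatteringCurve(x, y, md)


# --- HDF5 containers --------------------------------------------------------

def write_grid(grid: ReciprocalGrid, path) -> None:
    """Persist a reciprocal grid: shell q table, layout, interleaved re/im values."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["q_max"] = grid.q_max
        f.attrs["n_shells"] = grid.n_shells
        f.create_dataset("shell_q", data=np.array(
            [grid.shell_q(i) for i in range(grid.n_shells + 1)]))
        flat = np.concatenate([s.ravel() for s in grid.shells])
        f.create_dataset("values_real", data=flat.real)
        f.create_dataset("values_imag", data=flat.imag)


def read_grid(path) -> ReciprocalGrid:
    with h5py.File(path, "r") as f:
        q_max = float(f.attrs["q_max"])
        n_shells = int(f.attrs["n_shells"])
        flat = f["values_real"][:] + 1j * f["values_imag"][:]
    shells = []
    off = 0
    for i in range(n_shells + 1):
        shape = ReciprocalGrid.shell_shape(i)
        size = shape[0] * shape[1]
        shells.append(flat[off:off + size].reshape(shape))
        off += size
    if off != flat.size:
        raise ValidationError("grid file value count does not match its layout")
    return ReciprocalGrid(q_max, n_shells, shells)


def write_image(image: DetectorImage, path) -> None:
    """Persist a detector image: matrix, axes, mask and metadata attributes."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["q_limit"] = image.q_limit
        f.attrs["phi_prime"] = image.phi_prime
        for k, v in image.metadata.items():
            if isinstance(v, (bool, int, float, str)):
                f.attrs[f"meta_{k}"] = v
        f.create_dataset("values", data=image.values)
        f.create_dataset("q_perp_axis", data=image.q_perp_axis)
        f.create_dataset("q_z_axis", data=image.q_z_axis)
        if image.mask is not None:
            f.create_dataset("mask", data=image.mask.astype(np.uint8))


def read_image(path) -> DetectorImage:
    with h5py.File(path, "r") as f:
        vals = f["values"][:]
        qp = f["q_perp_axis"][:]
        qz = f["q_z_axis"][:]
        mask = f["mask"][:].astype(bool) if "mask" in f else None
        md = {k[5:]: (v.item() if hasattr(v, "item") else v)
              for k, v in f.attrs.items() if k.startswith("meta_")}
        return DetectorImage(vals, qp, qz, float(f.attrs["q_limit"]),
                             float(f.attrs["phi_prime"]), mask, md)
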