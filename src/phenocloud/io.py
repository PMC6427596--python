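"""Point-cloud file I/O: PLY (ascii / binary little-endian) and XYZ text.

Only the ``vertex`` element of PLY is interpreted; coordinates are written as
64-bit doubles so a binary round-trip is bitwise exact. XYZ files are plain
whitespace-delimited rows with at least three numeric columns; ``#`` comment
lines are skipped and extra columns are ignored.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np

from .core import PointCloud
from .errors import EmptyCloudError, ParameterError, ParseError

__all__ = ["read_cloud", "write_cloud"]

_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _detect_format(path: Path) -> str:
    with open(path, "rb") as fh:
        magic = fh.read(3)
    return "ply" if magic == b"ply" else "xyz"


def read_cloud(path: str | Path, format: str = "auto") -> PointCloud:
    """Read a PLY or XYZ file into a :class:`PointCloud`.

    Ids are assigned 0..N-1 in file order. ``format="auto"`` sniffs the
    magic bytes. Extra PLY vertex properties and extra XYZ columns are
    ignored; ``nx, ny, nz`` properties become normals.
    """
    path = Path(path)
    if format not in ("ply", "xyz", "auto"):
        raise ParameterError(f"unknown format {format!r}")
    if format == "auto":
        format = _detect_format(path)
    if format == "ply":
        pts, normals = _read_ply(path)
    else:
        pts, normals = _read_xyz(path), None
    if len(pts) == 0:
        raise EmptyCloudError(f"{path}: file contains no points")
    if normals is not None:
        norms = np.linalg.norm(normals, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            normals = np.where(norms > 0, normals / norms, [0.0, 0.0, 1.0])
    return PointCloud(pts, normals=normals)


def _read_xyz(path: Path) -> np.ndarray:
    rows = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            cols = stripped.split()
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                rows.append([float(c) for c in cols[:3]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value") from exc
    return np.asarray(rows, dtype=np.float64).reshape(-1, 3)


def _read_ply(path: Path) -> tuple[np.ndarray, np.ndarray | None]:
    with open(path, "rb") as fh:
        header_lines = []
        while True:
            line = fh.readline()
            if not line:
                raise ParseError(f"{path}: unexpected EOF in header")
            header_lines.append(line.decode("ascii", "replace").strip())
            if header_lines[-1] == "end_header":
                break
        body = fh.read()

    if header_lines[0] != "ply":
        raise ParseError(f"{path}:1: missing 'ply' magic")
    fmt = None
    elements: list[tuple[str, int, list[tuple[str, str]]]] = []
    for lineno, line in enumerate(header_lines[1:], start=2):
        tok = line.split()
        if not tok or tok[0] == "comment":
            continue
        if tok[0] == "format":
            if tok[1] not in ("ascii", "binary_little_endian"):
                raise ParseError(
                    f"{path}:{lineno}: unsupported format {tok[1]!r}")
            fmt = tok[1]
        elif tok[0] == "element":
            elements.append((tok[1], int(tok[2]), []))
        elif tok[0] == "property":
            if not elements:
                raise ParseError(f"{path}:{lineno}: property before element")
            if tok[1] == "list":
                raise ParseError(
                    f"{path}:{lineno}: list properties are not supported")
            if tok[1] not in _PLY_DTYPES:
                raise ParseError(f"{path}:{lineno}: unknown type {tok[1]!r}")
            elements[-1][2].append((tok[-1], _PLY_DTYPES[tok[1]]))
        elif tok[0] == "end_header":
            break
        else:
            raise ParseError(f"{path}:{lineno}: unrecognized keyword {tok[0]!r}")
    if fmt is None:
        raise ParseError(f"{path}: header has no 'format' line")

    vert = next((e for e in elements if e[0] == "vertex"), None)
    if vert is None:
        raise ParseError(f"{path}: no 'vertex' element")
    _, count, props = vert
    names = [p[0] for p in props]
    for ax in "xyz":
        if ax not in names:
            raise ParseError(f"{path}: vertex element lacks property '{ax}'")

    dtype = np.dtype([(n, "<" + t) for n, t in props])
    if fmt == "binary_little_endian":
        if elements[0][0] != "vertex":
            raise ParseError(f"{path}: binary PLY must lead with vertex element")
        need = dtype.itemsize * count
        if len(body) < need:
            raise ParseError(f"{path}: truncated binary vertex data")
        rec = np.frombuffer(body[:need], dtype=dtype)
    else:
        text = body.decode("ascii", "replace")
        rec = np.zeros(count, dtype=dtype)
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if len(lines) < count:
            raise ParseError(f"{path}: expected {count} vertex rows, "
                             f"found {len(lines)}")
        for i in range(count):
            cols = lines[i].split()
            if len(cols) < len(props):
                raise ParseError(f"{path}: vertex row {i + 1} too short")
            try:
                for (name, _), val in zip(props, cols):
                    rec[name][i] = float(val)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: vertex row {i + 1}: non-numeric value") from exc

    pts = np.column_stack([rec["x"], rec["y"], rec["z"]]).astype(np.float64)
    normals = None
    if all(n in names for n in ("nx", "ny", "nz")):
        normals = np.column_stack(
            [rec["nx"], rec["ny"], rec["nz"]]).astype(np.float64)
    return pts, normals


def write_cloud(cloud: PointCloud, path: str | Path, format: str = "ply",
                binary: bool = True) -> None:
    """Write a cloud as PLY (double precision) or XYZ text."""
    if len(cloud) == 0:
        raise EmptyCloudError("refusing to write an empty cloud")
    path = Path(path)
    if format == "xyz":
        np.savetxt(path, cloud.points, fmt="%.9f")
        return
    if format != "ply":
        raise ParameterError(f"unknown format {format!r}")

    names = ["x", "y", "z"]
    arrays = [cloud.points[:, 0], cloud.points[:, 1], cloud.points[:, 2]]
    if cloud.normals is not None:
        names += ["nx", "ny", "nz"]
        arrays += [cloud.normals[:, 0], cloud.normals[:, 1],
                   cloud.normals[:, 2]]

    fmt_line = "binary_little_endian" if binary else "ascii"
    header = ["ply", f"format {fmt_line} 1.0",
              f"element vertex {len(cloud)}"]
    header += [f"property double {n}" for n in names]
    header.append("end_header")

    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            rec = np.zeros(len(cloud),
                           dtype=np.dtype([(n, "<f8") for n in names]))
            for n, a in zip(names, arrays):
                rec[n] = a
            fh.write(rec.tobytes())
        else:
            buf = _io.StringIO()
            np.savetxt(buf, np.column_stack(arrays), fmt="%.17g")
            fh.write(buf.getvalue().encode("ascii"))
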