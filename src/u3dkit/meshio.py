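"""Wavefront OBJ and ASCII PLY triangle-mesh input (and a small OBJ writer).

Both readers cover the plain-geometry subset that matters for export:
positions, faces (fan-triangulated when they have more than three vertices)
and, for OBJ, optional per-vertex normals. Everything else is skipped — OBJ
skips with a counted warning, PLY ignores extra per-vertex properties.
"""

from __future__ import annotations

import warnings
from collections import Counter
from typing import IO, Iterable

import numpy as np

from .errors import U3DDataError, U3DWarning
from .scene import MeshGeometry

__all__ = ["read_obj", "read_ply_ascii", "write_obj"]


def _lines(stream: IO[str] | str | Iterable[str]):
    if isinstance(stream, str):
        yield from stream.splitlines()
    else:
        for line in stream:
            yield line.rstrip("\r\n")


def _resolve_obj_index(token: str, count: int, lineno: int, what: str) -> int:
    """OBJ indices are 1-based; negative indices count back from the most
    recently defined element."""
    try:
        idx = int(token)
    except ValueError:
        raise U3DDataError(f"non-integer {what} index {token!r}",
                           row=lineno) from None
    if idx > 0:
        out = idx - 1
    elif idx < 0:
        out = count + idx
    else:
        raise U3DDataError(f"{what} index 0 is not valid in OBJ", row=lineno)
    if not 0 <= out < count:
        raise U3DDataError(
            f"{what} index {idx} references nonexistent element "
            f"(only {count} defined)", row=lineno)
    return out


def _fan(indices: list) -> list[tuple]:
    return [(indices[0], indices[k], indices[k + 1])
            for k in range(1, len(indices) - 1)]


def read_obj(stream) -> MeshGeometry:
    """Read the ``v`` / ``vn`` / ``f`` subset of an ASCII Wavefront OBJ.

    Faces with more than three vertices are fan-triangulated from their
    first vertex. Other record types are ignored and counted into a single
    warning. Normals are carried over only when every face corner has a
    normal reference and each vertex is always paired with the same normal;
    otherwise they are dropped (computable downstream).
    """
    positions: list[tuple[float, float, float]] = []
    normals: list[tuple[float, float, float]] = []
    faces: list[tuple[int, int, int]] = []
    corner_normals: list[tuple[int, int, int] | None] = []
    ignored: Counter[str] = Counter()
    for lineno, raw in enumerate(_lines(stream), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        rec, args = parts[0], parts[1:]
        if rec == "v":
            if len(args) < 3:
                raise U3DDataError("vertex needs 3 coordinates", row=lineno)
            try:
                positions.append(tuple(float(a) for a in args[:3]))
            except ValueError:
                raise U3DDataError(f"non-numeric vertex {line!r}",
                                   row=lineno) from None
        elif rec == "vn":
            if len(args) < 3:
                raise U3DDataError("normal needs 3 components", row=lineno)
            normals.append(tuple(float(a) for a in args[:3]))
        elif rec == "f":
            if len(args) < 3:
                raise U3DDataError("face needs >= 3 vertices", row=lineno)
            vidx, nidx = [], []
            for token in args:
                sub = token.split("/")
                vidx.append(_resolve_obj_index(sub[0], len(positions),
                                               lineno, "vertex"))
                if len(sub) >= 3 and sub[2]:
                    nidx.append(_resolve_obj_index(sub[2], len(normals),
                                                   lineno, "normal"))
                else:
                    nidx.append(None)
            for tri in _fan(list(range(len(vidx)))):
                faces.append(tuple(vidx[k] for k in tri))
                if all(nidx[k] is not None for k in tri):
                    corner_normals.append(tuple(nidx[k] for k in tri))
                else:
                    corner_normals.append(None)
        else:
            ignored[rec] += 1
    if ignored:
        total = sum(ignored.values())
        kinds = ", ".join(f"{k} x{v}" for k, v in sorted(ignored.items()))
        warnings.warn(f"ignored {total} unsupported OBJ record(s): {kinds}",
                      U3DWarning, stacklevel=2)
    per_vertex = _per_vertex_normals(positions, normals, faces, corner_normals)
    return MeshGeometry(positions=np.asarray(positions, dtype=np.float64
                                             ).reshape(-1, 3),
                        faces=np.asarray(faces, dtype=np.int64
                                         ).reshape(-1, 3),
                        normals=per_vertex)


def _per_vertex_normals(positions, normals, faces, corner_normals):
    if not faces or not normals or any(cn is None for cn in corner_normals):
        return None
    assignment: dict[int, int] = {}
    for face, cn in zip(faces, corner_normals):
        for v, n in zip(face, cn):
            if assignment.setdefault(v, n) != n:
                warnings.warn(
                    "OBJ normals are per-corner, not per-vertex; dropping "
                    "them (they can be recomputed)", U3DWarning, stacklevel=3)
                return None
    if len(assignment) < len(positions):
        return None
    arr = np.asarray([normals[assignment[v]] for v in range(len(positions))],
                     dtype=np.float64)
    lens = np.linalg.norm(arr, axis=1)
    if np.any(lens < 1e-30):
        return None
    return arr / lens[:, None]


def write_obj(mesh: MeshGeometry, stream) -> None:
    """Write a mesh as ASCII OBJ (fixture writer; inverse of read_obj)."""
    for x, y, z in mesh.positions:
        stream.write(f"v {float(x)!r} {float(y)!r} {float(z)!r}\n")
    if mesh.normals is not None:
        for x, y, z in mesh.normals:
            stream.write(f"vn {float(x)!r} {float(y)!r} {float(z)!r}\n")
        for a, b, c in mesh.faces:
            stream.write(f"f {a+1}//{a+1} {b+1}//{b+1} {c+1}//{c+1}\n")
    else:
        for a, b, c in mesh.faces:
            stream.write(f"f {a+1} {b+1} {c+1}\n")


def read_ply_ascii(stream) -> MeshGeometry:
    """Read an ASCII PLY mesh: vertex x/y/z plus a face vertex-index list.

    Extra per-vertex properties are ignored. Binary PLY is rejected with an
    error naming the detected format. Faces with more than three vertices
    are fan-triangulated.
    """
    lines = _lines(stream)
    try:
        magic = next(lines).strip()
    except StopIteration:
        raise U3DDataError("empty PLY stream") from None
    if magic != "ply":
        raise U3DDataError("not a PLY file (missing 'ply' magic)")
    elements: list[tuple[str, int, list[str]]] = []  # (name, count, props)
    fmt = None
    current_props: list[str] | None = None
    for lineno, raw in enumerate(lines, start=2):
        line = raw.strip()
        if not line or line.startswith("comment"):
            continue
        parts = line.split()
        if parts[0] == "format":
            fmt = parts[1]
            if fmt != "ascii":
                raise U3DDataError(
                    f"unsupported PLY format {fmt!r}: only ascii is readable")
        elif parts[0] == "element":
            current_props = []
            elements.append((parts[1], int(parts[2]), current_props))
        elif parts[0] == "property":
            if current_props is None:
                raise U3DDataError("property before element in PLY header",
                                   row=lineno)
            current_props.append(parts[-1])
        elif parts[0] == "end_header":
            break
        else:
            raise U3DDataError(f"unknown PLY header line {line!r}", row=lineno)
    else:
        raise U3DDataError("PLY header has no end_header")
    if fmt is None:
        raise U3DDataError("PLY header has no format line")

    body = [ln.strip() for ln in lines if ln.strip()]
    cursor = 0
    positions = np.zeros((0, 3))
    faces: list[tuple[int, int, int]] = []
    for name, count, props in elements:
        if cursor + count > len(body):
            raise U3DDataError(
                f"PLY body ends early: element {name!r} declares {count} "
                f"rows but only {len(body) - cursor} remain")
        rows = body[cursor:cursor + count]
        cursor += count
        if name == "vertex":
            try:
                cols = [props.index(axis) for axis in ("x", "y", "z")]
            except ValueError:
                raise U3DDataError(
                    "PLY vertex element lacks x/y/z properties") from None
            data = []
            for lineno, row in enumerate(rows):
                fields = row.split()
                if len(fields) < len(props):
                    raise U3DDataError(
                        f"PLY vertex row has {len(fields)} fields, "
                        f"header declares {len(props)}")
                data.append(tuple(float(fields[c]) for c in cols))
            positions = np.asarray(data, dtype=np.float64).reshape(-1, 3)
        elif name == "face":
            for row in rows:
                fields = row.split()
                n = int(fields[0])
                if len(fields) < n + 1:
                    raise U3DDataError(
                        f"PLY face row declares {n} indices but carries "
                        f"{len(fields) - 1}")
                idx = [int(f) for f in fields[1:n + 1]]
                if n < 3:
                    raise U3DDataError("PLY face needs >= 3 vertices")
                faces.extend(_fan(idx))
        # other elements: skipped
    for a, b, c in faces:
        if not all(0 <= v < len(positions) for v in (a, b, c)):
            raise U3DDataError(
                f"PLY face ({a},{b},{c}) references nonexistent vertex")
    return MeshGeometry(positions=positions,
                        faces=np.asarray(faces, dtype=np.int64).reshape(-1, 3))
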