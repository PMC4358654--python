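"""Deterministic synthetic geometry and scenes for tests, demos and benchmarks.

``make_fixture`` produces the four canonical shapes used throughout the test
suite: a lattice point cloud, a helix polyline (a stand-in for trajectory
data such as vectorcardiogram loops), a cube and a subdivided-icosahedron
sphere. ``random_scene`` assembles small randomized scenes — mixed geometry
kinds, nested groups, shared resources, metadata — for fuzz-style
structural testing.
"""

from __future__ import annotations

import numpy as np

from .errors import U3DConfigError
from .scene import (LineSetGeometry, MeshGeometry, PointCloudGeometry, Scene,
                    add_model, compute_vertex_normals)
from .specs import ObjectSpec, apply_defaults
from .tabular import auto_connect

__all__ = ["make_fixture", "random_scene", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("grid_points", "helix_line", "cube_mesh", "sphere_mesh")

# Unit cube corners; faces CCW seen from outside.
_CUBE_POSITIONS = np.array(
    [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
     [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=np.float64)
_CUBE_FACES = np.array(
    [[0, 2, 1], [0, 3, 2],          # bottom (z=0), normal -z
     [4, 5, 6], [4, 6, 7],          # top (z=1), normal +z
     [0, 1, 5], [0, 5, 4],          # front (y=0), normal -y
     [2, 3, 7], [2, 7, 6],          # back (y=1), normal +y
     [0, 4, 7], [0, 7, 3],          # left (x=0), normal -x
     [1, 2, 6], [1, 6, 5]], dtype=np.int64)   # right (x=1), normal +x


def _grid_points(params, rng) -> PointCloudGeometry:
    nx = int(params.get("nx", 3))
    ny = int(params.get("ny", 3))
    nz = int(params.get("nz", 3))
    spacing = float(params.get("spacing", 1.0))
    jitter = float(params.get("jitter", 0.0))
    if min(nx, ny, nz) < 1 or spacing <= 0 or jitter < 0:
        raise U3DConfigError("grid_points needs nx,ny,nz >= 1, spacing > 0")
    axes = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                       indexing="ij")
    pts = np.stack([a.ravel() for a in axes], axis=1) * spacing
    if jitter > 0:
        pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
    return PointCloudGeometry(positions=pts)


def _helix_line(params, rng) -> LineSetGeometry:
    n = int(params.get("n_samples", 100))
    turns = float(params.get("turns", 3.0))
    radius = float(params.get("radius", 1.0))
    height = float(params.get("height", 2.0))
    if n < 1:
        raise U3DConfigError("helix_line needs n_samples >= 1")
    t = np.linspace(0.0, 1.0, n)
    pts = np.column_stack([radius * np.cos(2 * np.pi * turns * t),
                           radius * np.sin(2 * np.pi * turns * t),
                           height * t])
    return LineSetGeometry(positions=pts, edges=auto_connect(n))


def _cube_mesh(params, rng) -> MeshGeometry:
    size = float(params.get("size", 1.0))
    mesh = MeshGeometry(positions=_CUBE_POSITIONS * size, faces=_CUBE_FACES)
    return compute_vertex_normals(mesh) if params.get("normals", True) else mesh


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1]],
        dtype=np.float64)
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1]],
        dtype=np.int64)
    return verts, faces


def _sphere_mesh(params, rng) -> MeshGeometry:
    subdivisions = int(params.get("subdivisions", 2))
    radius = float(params.get("radius", 1.0))
    if subdivisions < 0 or radius <= 0:
        raise U3DConfigError("sphere_mesh needs subdivisions >= 0, radius > 0")
    verts, faces = _icosahedron()
    verts = verts / np.linalg.norm(verts, axis=1)[:, None]
    for _ in range(subdivisions):
        vlist = [tuple(v) for v in verts]
        cache: dict[tuple[int, int], int] = {}

        def midpoint(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key not in cache:
                m = (verts[a] + verts[b]) / 2.0
                m = m / np.linalg.norm(m)
                cache[key] = len(vlist)
                vlist.append(tuple(m))
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces.extend([(a, ab, ca), (b, bc, ab), (c, ca, bc),
                              (ab, bc, ca)])
        verts = np.asarray(vlist, dtype=np.float64)
        faces = np.asarray(new_faces, dtype=np.int64)
    mesh = MeshGeometry(positions=verts * radius, faces=faces)
    return compute_vertex_normals(mesh)


_BUILDERS = {"grid_points": _grid_points, "helix_line": _helix_line,
             "cube_mesh": _cube_mesh, "sphere_mesh": _sphere_mesh}


def make_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Build one deterministic geometry resource of the requested kind.

    ``seed`` only matters for kinds with stochastic parameters (e.g.
    ``grid_points`` with ``jitter > 0``); everything else is closed-form.
    """
    if kind not in _BUILDERS:
        raise U3DConfigError(
            f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    rng = np.random.default_rng(seed)
    return _BUILDERS[kind](dict(params or {}), rng)


def random_scene(seed: int, max_objects: int = 3) -> Scene:
    """A small randomized but reproducible scene for structural fuzzing."""
    rng = np.random.default_rng(seed)
    scene = Scene()
    n_objects = int(rng.integers(1, max_objects + 1))
    groups = ["/", "A", "A/B", "C"]
    kind_type = {"grid_points": "pointset", "helix_line": "lineset",
                 "cube_mesh": "mesh", "sphere_mesh": "mesh"}
    resources: list[tuple[str, str]] = []   # (resource_id, object_type)
    for i in range(n_objects):
        kind = FIXTURE_KINDS[int(rng.integers(0, len(FIXTURE_KINDS)))]
        share = resources and rng.random() < 0.3
        if share:
            rid, otype = resources[int(rng.integers(0, len(resources)))]
        else:
            params = {}
            if kind == "grid_points":
                params = {"nx": int(rng.integers(1, 4)),
                          "ny": int(rng.integers(1, 4)),
                          "nz": int(rng.integers(1, 4)),
                          "jitter": float(rng.random() * 0.2)}
            elif kind == "helix_line":
                params = {"n_samples": int(rng.integers(2, 40))}
            elif kind == "sphere_mesh":
                params = {"subdivisions": 0}
            rid = f"geo_{len(resources)}"
            otype = kind_type[kind]
            scene.add_resource(rid, make_fixture(kind, params,
                                                 seed=int(rng.integers(2**31))))
            resources.append((rid, otype))
        spec = apply_defaults(ObjectSpec(
            object_type=otype, geometry_id=rid,
            name=f"obj_{i}",
            group_path=groups[int(rng.integers(0, len(groups)))],
            diffuse=tuple(np.round(rng.random(3), 3)),
            opacity=float(rng.choice([1.0, 1.0, 0.5, 0.25])),
        ))
        add_model(scene, spec, rid)
    if rng.random() < 0.5:
        scene.metadata.append(("Title", f"random scene {seed}"))
    return scene
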