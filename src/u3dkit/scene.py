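"""In-memory scene model: geometry resources, node tree, materials, metadata.

The scene is the hub of the package: importers produce geometry resources,
the object-specification language describes how they become visible objects,
and the encoder serializes the whole thing to a U3D byte stream.

Geometry coordinates are stored as 32-bit floats because that is the
precision the U3D container carries; coordinates are passed through
unchanged otherwise (a right-handed coordinate system is assumed, matching
U3D viewers — axis conventions are the producer's responsibility).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import U3DStructureError, U3DWarning

__all__ = [
    "ColorRGBA", "Material", "PointCloudGeometry", "LineSetGeometry",
    "MeshGeometry", "SceneNode", "Scene", "GeometryIssue",
    "add_group_path", "add_model", "compute_vertex_normals",
    "validate_geometry", "default_material",
]


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, float(x)))


@dataclass(frozen=True)
class ColorRGBA:
    """RGBA color; channels are clamped into [0, 1] on construction."""

    r: float = 0.0
    g: float = 0.0
    b: float = 0.0
    a: float = 1.0

    def __post_init__(self):
        for ch in "rgba":
            object.__setattr__(self, ch, _clamp01(getattr(self, ch)))

    def rgb(self) -> tuple[float, float, float]:
        return (self.r, self.g, self.b)


@dataclass(frozen=True)
class Material:
    """Constant (per-object) surface appearance.

    ``opacity`` < 1 makes the encoder enable the alpha-blending path in the
    emitted shader so viewers render the object transparent.
    """

    diffuse: ColorRGBA = ColorRGBA(0.65, 0.65, 0.65)
    specular: ColorRGBA = ColorRGBA(0.3, 0.3, 0.3)
    ambient: ColorRGBA = ColorRGBA(0.065, 0.065, 0.065)
    emissive: ColorRGBA = ColorRGBA(0.0, 0.0, 0.0)
    reflectivity: float = 0.0
    opacity: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "reflectivity", _clamp01(self.reflectivity))
        object.__setattr__(self, "opacity", _clamp01(self.opacity))

    def key(self) -> tuple:
        """Value identity used to share one on-disk resource per material."""
        cols = (self.diffuse, self.specular, self.ambient, self.emissive)
        return tuple((c.r, c.g, c.b, c.a) for c in cols) + (
            self.reflectivity, self.opacity)


def default_material(diffuse=(0.65, 0.65, 0.65), opacity=1.0,
                     specular=(0.3, 0.3, 0.3)) -> Material:
    """Build a material from the configurable default table.

    Ambient is 0.1 x diffuse, emissive black, reflectivity 0 unless stated.
    """
    d = ColorRGBA(*diffuse)
    return Material(
        diffuse=d,
        specular=ColorRGBA(*specular),
        ambient=ColorRGBA(0.1 * d.r, 0.1 * d.g, 0.1 * d.b),
        emissive=ColorRGBA(0, 0, 0),
        reflectivity=0.0,
        opacity=float(opacity),
    )


def _as_positions(positions) -> np.ndarray:
    arr = np.asarray(positions, dtype=np.float32)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise U3DStructureError(
            f"positions must be an (N, 3) array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise U3DStructureError("positions contain NaN or Inf")
    return arr


def _as_index_array(indices, width: int, what: str) -> np.ndarray:
    arr = np.asarray(indices, dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, width).astype(np.int32)
    if arr.ndim != 2 or arr.shape[1] != width:
        raise U3DStructureError(
            f"{what} must be an (N, {width}) array, got shape {arr.shape}")
    return arr.astype(np.int32)


@dataclass
class PointCloudGeometry:
    """Bare 3D positions — the simplest geometry kind."""

    positions: np.ndarray

    def __post_init__(self):
        self.positions = _as_positions(self.positions)


@dataclass
class LineSetGeometry:
    """Positions joined by edges (polylines); edges are 0-based index pairs."""

    positions: np.ndarray
    edges: np.ndarray

    def __post_init__(self):
        self.positions = _as_positions(self.positions)
        self.edges = _as_index_array(self.edges, 2, "edges")


@dataclass
class MeshGeometry:
    """Triangle mesh: positions, 0-based face triples, optional unit normals."""

    positions: np.ndarray
    faces: np.ndarray
    normals: np.ndarray | None = None

    def __post_init__(self):
        self.positions = _as_positions(self.positions)
        self.faces = _as_index_array(self.faces, 3, "faces")
        if self.normals is not None:
            self.normals = _as_positions(self.normals)


GeometryResource = PointCloudGeometry | LineSetGeometry | MeshGeometry


@dataclass
class SceneNode:
    """A node of the object tree: a named group or a model.

    Groups carry children; models carry a geometry reference and a material.
    Names are unique among siblings (enforced on insertion).
    """

    kind: str                      # "group" | "model"
    name: str
    children: list["SceneNode"] = field(default_factory=list)
    geometry_ref: str | None = None
    material: Material | None = None
    transform: np.ndarray = field(
        default_factory=lambda: np.eye(4, dtype=np.float32))

    def child(self, name: str) -> "SceneNode | None":
        for c in self.children:
            if c.name == name:
                return c
        return None

    def walk(self):
        """Yield this node and all descendants depth-first (pre-order)."""
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class Scene:
    """Root group + geometry-resource table + file-level metadata.

    A geometry resource may be referenced by any number of model nodes; it is
    serialized once regardless, which is what keeps files with repeated
    shapes small.
    """

    root: SceneNode = field(
        default_factory=lambda: SceneNode(kind="group", name="Scene"))
    resources: dict[str, GeometryResource] = field(default_factory=dict)
    metadata: list[tuple[str, str]] = field(default_factory=list)

    def add_resource(self, resource_id: str, resource: GeometryResource) -> str:
        if not resource_id:
            raise U3DStructureError("resource id must be non-empty")
        if resource_id in self.resources:
            raise U3DStructureError(f"duplicate resource id {resource_id!r}")
        self.resources[resource_id] = resource
        return resource_id

    def model_nodes(self) -> list[SceneNode]:
        return [n for n in self.root.walk() if n.kind == "model"]


def add_group_path(scene: Scene, path: str) -> SceneNode:
    """Ensure all groups along a '/'-separated path exist; return the deepest.

    Existing groups are reused, so the operation is idempotent. ``"/"``
    denotes the root group itself. Colliding with an existing *model* node is
    a structural error.
    """
    if path == "":
        raise U3DStructureError("group path must be non-empty")
    if path == "/":
        return scene.root
    names = path.strip("/").split("/")
    if any(n == "" for n in names):
        raise U3DStructureError(f"group path {path!r} has an empty segment")
    node = scene.root
    for name in names:
        existing = node.child(name)
        if existing is None:
            existing = SceneNode(kind="group", name=name)
            node.children.append(existing)
        elif existing.kind != "group":
            raise U3DStructureError(
                f"path segment {name!r} collides with a model node")
        node = existing
    return node


def _unique_sibling_name(parent: SceneNode, name: str) -> str:
    if parent.child(name) is None:
        return name
    i = 2
    while parent.child(f"{name}_{i}") is not None:
        i += 1
    return f"{name}_{i}"


def add_model(scene: Scene, spec, geometry_ref: str) -> SceneNode:
    """Attach a model node described by an ObjectSpec.

    ``spec`` needs ``name``, ``group_path``, ``diffuse``, ``specular`` and
    ``opacity`` attributes (see :mod:`u3dkit.specs`). Duplicate sibling names
    are auto-suffixed ``_2``, ``_3``... with a warning rather than aborting
    the export over a cosmetic clash.
    """
    if geometry_ref not in scene.resources:
        raise U3DStructureError(
            f"geometry reference {geometry_ref!r} does not resolve")
    if not getattr(spec, "name", None):
        raise U3DStructureError("object spec has no name")
    parent = add_group_path(scene, getattr(spec, "group_path", "/") or "/")
    name = _unique_sibling_name(parent, spec.name)
    if name != spec.name:
        warnings.warn(
            f"sibling name clash: {spec.name!r} renamed to {name!r}",
            U3DWarning, stacklevel=2)
    node = SceneNode(
        kind="model", name=name, geometry_ref=geometry_ref,
        material=default_material(diffuse=spec.diffuse, opacity=spec.opacity,
                                  specular=spec.specular))
    parent.children.append(node)
    return node


def compute_vertex_normals(mesh: MeshGeometry) -> MeshGeometry:
    """Per-vertex normals as the normalized area-weighted mean of face normals.

    Face normals follow the counter-clockwise right-hand winding rule. The
    cross product of two triangle edges has magnitude twice the face area, so
    accumulating raw cross products per incident vertex *is* the
    area-weighted average before normalization. Existing normals are
    preserved untouched; vertices whose incident faces all have zero area get
    the (0, 0, 1) fallback with a warning.
    """
    if mesh.normals is not None:
        return mesh
    issues = validate_geometry(mesh)
    blocking = [i for i in issues if not i.droppable]
    if blocking:
        raise U3DStructureError(
            "mesh fails index validity: " + "; ".join(i.message for i in blocking))
    pos = mesh.positions.astype(np.float64)
    faces = mesh.faces
    acc = np.zeros_like(pos)
    if len(faces):
        e1 = pos[faces[:, 1]] - pos[faces[:, 0]]
        e2 = pos[faces[:, 2]] - pos[faces[:, 0]]
        fn = np.cross(e1, e2)          # |fn| = 2 * face area
        for k in range(3):
            np.add.at(acc, faces[:, k], fn)
    norms = np.linalg.norm(acc, axis=1)
    degenerate = norms < 1e-30
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} vertex normal(s) undefined "
            "(zero-area incidence); using (0, 0, 1) fallback",
            U3DWarning, stacklevel=2)
        acc[degenerate] = (0.0, 0.0, 1.0)
        norms[degenerate] = 1.0
    unit = acc / norms[:, None]
    return replace(mesh, normals=unit.astype(np.float32))


@dataclass(frozen=True)
class GeometryIssue:
    """One finding from validate_geometry."""

    code: str          # "degenerate_face" | "index_out_of_range" | ...
    message: str
    index: int         # element index the issue refers to (-1: whole resource)
    droppable: bool    # True if dropping the element repairs the resource


def validate_geometry(resource: GeometryResource) -> list[GeometryIssue]:
    """Report every type-invariant violation; empty list means valid.

    Degenerate faces (repeated vertex index) and zero-length edges are
    flagged droppable — the encoder drops them with a warning before export.
    """
    issues: list[GeometryIssue] = []
    n = len(resource.positions)
    if isinstance(resource, LineSetGeometry):
        for i, (a, b) in enumerate(resource.edges):
            if not (0 <= a < n and 0 <= b < n):
                issues.append(GeometryIssue(
                    "index_out_of_range",
                    f"edge {i} ({a},{b}) index out of range for {n} positions",
                    i, False))
            elif a == b:
                issues.append(GeometryIssue(
                    "degenerate_edge", f"edge {i} joins vertex {a} to itself",
                    i, True))
    elif isinstance(resource, MeshGeometry):
        for i, f in enumerate(resource.faces):
            a, b, c = (int(x) for x in f)
            if not all(0 <= v < n for v in (a, b, c)):
                issues.append(GeometryIssue(
                    "index_out_of_range",
                    f"face {i} ({a},{b},{c}) index out of range for "
                    f"{n} positions", i, False))
            elif a == b or b == c or a == c:
                issues.append(GeometryIssue(
                    "degenerate_face",
                    f"degenerate face {i} repeats a vertex index", i, True))
        if resource.normals is not None:
            if len(resource.normals) != n:
                issues.append(GeometryIssue(
                    "normal_count_mismatch",
                    f"{len(resource.normals)} normals for {n} positions",
                    -1, False))
            else:
                lens = np.linalg.norm(
                    resource.normals.astype(np.float64), axis=1)
                bad = np.nonzero(np.abs(lens - 1.0) > 1e-6)[0]
                for i in bad:
                    issues.append(GeometryIssue(
                        "non_unit_normal",
                        f"normal {int(i)} has length {lens[i]:.8f}",
                        int(i), False))
    return issues
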