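"""Serialize a Scene to an ECMA-363 U3D byte stream.

File layout: a file-header block (carrying the scene metadata), a
declaration section (geometry declaration chains, shader/material
resources, optional light/view resources, node chains), then the
continuation section with the bulk geometry payload. Every block is
32-bit aligned and declares its unpadded sizes; the header's declared
declaration/file sizes are patched after assembly so they match the final
stream exactly. Output is byte-identical across runs for identical input —
no timestamps are written unless supplied as metadata.

Geometry payload strategy (full-resolution export, no progressive levels):

* meshes — a CLOD declaration whose minimum and maximum resolution both
  equal the vertex count, plus one base-mesh continuation. Positions and
  normals are 32-bit floats (bit-exact round trip); face corner indices use
  static compression contexts sized by the vertex count.
* point and line sets — positions are quantized (``round(x * factor)``)
  and coded as per-axis differences from the previously written position,
  sign bits and magnitudes in adaptive dynamic contexts. Inverse
  quantization bounds the per-axis error by ``0.5 / factor``.
* each edge of a line set is attached to its larger-index endpoint, so a
  polyline decodes position-major with (min, max)-oriented segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import constants as C
from .bitio import BitWriter
from .blocks import U3DBlock, serialize_blocks
from .errors import U3DEncodeError, U3DWarning
from .scene import (LineSetGeometry, Material, MeshGeometry,
                    PointCloudGeometry, Scene, SceneNode, validate_geometry,
                    compute_vertex_normals)

__all__ = ["QuantizationParams", "EncoderConfig", "write_file", "save_u3d",
           "encode_header_block", "encode_node_blocks", "encode_point_set",
           "encode_line_set", "encode_mesh", "encode_shading_resources",
           "encode_light_view_defaults"]


@dataclass(frozen=True)
class QuantizationParams:
    """Scale factors applied before integer-coding coordinates.

    The default position factor 1000 keeps roughly three decimal digits
    (per-axis error at most 5e-4 in model units). Only the position factor
    affects emitted geometry here — normals travel as raw floats and
    per-vertex colors/texcoords are not emitted — but all factors are
    recorded in declaration blocks.
    """

    position: float = 1000.0
    normal: float = 1024.0
    diffuse: float = 256.0
    specular: float = 256.0
    texcoord: float = 1024.0

    def __post_init__(self):
        for name in ("position", "normal", "diffuse", "specular", "texcoord"):
            if getattr(self, name) <= 0:
                raise U3DEncodeError(f"quantization factor {name} must be > 0")


@dataclass(frozen=True)
class EncoderConfig:
    quant: QuantizationParams = field(default_factory=QuantizationParams)
    emit_default_lighting: bool = False
    emit_default_view: bool = False
    root_node_name: str = "Scene"
    creator_metadata: tuple[tuple[str, str], ...] = ()
    include_normals: bool = True

    def __post_init__(self):
        if not self.root_node_name:
            raise U3DEncodeError("root_node_name must be non-empty")


# ---------------------------------------------------------------------------
# small helpers

_IDENTITY = np.eye(4, dtype=np.float64)


def _write_matrix(w: BitWriter, matrix) -> None:
    # Column-major, translation in the last column.
    m = np.asarray(matrix, dtype=np.float64)
    for col in range(4):
        for row in range(4):
            w.write_f32(float(m[row, col]))


def _metadata_bytes(pairs) -> bytes:
    if not pairs:
        return b""
    w = BitWriter()
    w.write_u32(len(pairs))
    for key, value in pairs:
        w.write_u32(0)                  # attributes: 0 = string value
        w.write_string(str(key))
        w.write_string(str(value))
    return w.finish()


def _quantize(positions: np.ndarray, factor: float) -> np.ndarray:
    q = np.rint(positions.astype(np.float64) * factor)
    if np.any(np.abs(q) >= 2 ** 31):
        raise U3DEncodeError(
            "quantized coordinate exceeds 32-bit range; lower the position "
            "quantization factor or rescale the data")
    return q.astype(np.int64)


def _write_quantized_diff(w: BitWriter, dq: np.ndarray) -> None:
    signs = (int(dq[0] < 0) | (int(dq[1] < 0) << 1) | (int(dq[2] < 0) << 2))
    w.write_compressed_u8(C.CTX_POS_DIFF_SIGN, signs)
    w.write_compressed_u32(C.CTX_POS_DIFF_X, int(abs(dq[0])))
    w.write_compressed_u32(C.CTX_POS_DIFF_Y, int(abs(dq[1])))
    w.write_compressed_u32(C.CTX_POS_DIFF_Z, int(abs(dq[2])))


def _begin(name: str, chain_index: int = 0) -> BitWriter:
    w = BitWriter()
    w.write_string(name)
    w.write_u32(chain_index)
    return w


def _shading_description(w: BitWriter) -> None:
    w.write_u32(1)      # shading count
    w.write_u32(0)      # shading attributes: no per-vertex colors
    w.write_u32(0)      # texture layer count
    w.write_u32(0)      # original shading id


def _resource_description(w: BitWriter, quant: QuantizationParams) -> None:
    w.write_u32(int(quant.position))   # quality factors (informational)
    w.write_u32(int(quant.normal))
    w.write_u32(int(quant.texcoord))
    w.write_f32(1.0 / quant.position)  # inverse quantization steps
    w.write_f32(1.0 / quant.normal)
    w.write_f32(1.0 / quant.texcoord)
    w.write_f32(1.0 / quant.diffuse)
    w.write_f32(1.0 / quant.specular)
    w.write_f32(0.9)                   # normal crease parameter
    w.write_f32(0.5)                   # normal update parameter
    w.write_f32(0.985)                 # normal tolerance parameter


# ---------------------------------------------------------------------------
# geometry encoders

def encode_point_set(resource: PointCloudGeometry, name: str,
                     quant: QuantizationParams) -> tuple[U3DBlock, U3DBlock]:
    """Point-set declaration + continuation; one point per position."""
    n = len(resource.positions)
    if n == 0:
        raise U3DEncodeError(f"point set {name!r} has no positions")
    d = _begin(name)
    d.write_u32(0)                     # reserved
    d.write_u32(n)                     # point count
    d.write_u32(n)                     # position count
    for _ in range(4):                 # normal/diffuse/specular/texcoord
        d.write_u32(0)
    _shading_description(d)
    _resource_description(d, quant)
    d.write_u32(0)                     # bone count
    decl = U3DBlock(C.BT_POINT_SET_DECL, d.finish())

    q = _quantize(resource.positions, quant.position)
    c = _begin(name)
    c.write_u32(0)                     # start resolution
    c.write_u32(n)                     # end resolution
    prev = np.zeros(3, dtype=np.int64)
    for i in range(n):
        c.write_compressed_u32(C.static_context(max(i, 1)),
                               i - 1 if i > 0 else 0)   # split position
        _write_quantized_diff(c, q[i] - prev)
        prev = q[i]
        c.write_compressed_u32(C.CTX_NORMAL_COUNT, 0)
        c.write_compressed_u32(C.CTX_POINT_COUNT, 1)
        c.write_compressed_u32(C.CTX_SHADING_ID, 0)
    return decl, U3DBlock(C.BT_POINT_SET_CONT, c.finish())


def encode_line_set(resource: LineSetGeometry, name: str,
                    quant: QuantizationParams) -> tuple[U3DBlock, U3DBlock]:
    """Line-set declaration + continuation.

    Zero-length edges must already have been dropped (``write_file`` does
    this with a warning); they cannot be attached to a strictly earlier
    endpoint.
    """
    n = len(resource.positions)
    if n == 0:
        raise U3DEncodeError(f"line set {name!r} has no positions")
    edges = np.asarray(resource.edges, dtype=np.int64).reshape(-1, 2)
    if len(edges) and (edges.min() < 0 or edges.max() >= n):
        raise U3DEncodeError(f"line set {name!r} has out-of-range edges")
    if np.any(edges[:, 0] == edges[:, 1]) if len(edges) else False:
        raise U3DEncodeError(
            f"line set {name!r} still contains zero-length edges")

    d = _begin(name)
    d.write_u32(0)                     # reserved
    d.write_u32(len(edges))            # line count
    d.write_u32(n)                     # position count
    for _ in range(4):
        d.write_u32(0)
    _shading_description(d)
    _resource_description(d, quant)
    d.write_u32(0)
    decl = U3DBlock(C.BT_LINE_SET_DECL, d.finish())

    # Attach each edge to its larger-index endpoint.
    attached: list[list[int]] = [[] for _ in range(n)]
    for a, b in edges:
        hi, lo = (int(a), int(b)) if a > b else (int(b), int(a))
        attached[hi].append(lo)

    q = _quantize(resource.positions, quant.position)
    c = _begin(name)
    c.write_u32(0)
    c.write_u32(n)
    prev = np.zeros(3, dtype=np.int64)
    for i in range(n):
        c.write_compressed_u32(C.static_context(max(i, 1)),
                               i - 1 if i > 0 else 0)
        _write_quantized_diff(c, q[i] - prev)
        prev = q[i]
        c.write_compressed_u32(C.CTX_NORMAL_COUNT, 0)
        c.write_compressed_u32(C.CTX_LINE_COUNT, len(attached[i]))
        for other in attached[i]:
            c.write_compressed_u32(C.static_context(i), other)
            c.write_compressed_u32(C.CTX_SHADING_ID, 0)
    return decl, U3DBlock(C.BT_LINE_SET_CONT, c.finish())


def encode_mesh(resource: MeshGeometry, name: str, quant: QuantizationParams,
                include_normals: bool = True) -> tuple[U3DBlock, U3DBlock]:
    """CLOD mesh declaration + single full-resolution base-mesh continuation.

    Minimum resolution = maximum resolution = vertex count: the mesh is a
    plain triangle mesh with no progressive updates, which is what
    final-resolution publication exports need.
    """
    n = len(resource.positions)
    nf = len(resource.faces)
    if n == 0:
        raise U3DEncodeError(f"mesh {name!r} has no positions")
    if len(resource.faces) and int(resource.faces.max()) >= n:
        raise U3DEncodeError(f"mesh {name!r} has out-of-range face indices")
    normals = resource.normals if include_normals else None
    if include_normals and normals is None:
        raise U3DEncodeError(
            f"mesh {name!r} has no normals; run compute_vertex_normals or "
            "exclude normals in the config")
    nn = n if normals is not None else 0

    d = _begin(name)
    d.write_u32(C.MESH_ATTR_DEFAULT if normals is not None
                else C.MESH_ATTR_EXCLUDE_NORMALS)
    d.write_u32(nf)                    # face count
    d.write_u32(n)                     # position count
    d.write_u32(nn)                    # normal count
    d.write_u32(0)                     # diffuse color count
    d.write_u32(0)                     # specular color count
    d.write_u32(0)                     # texture coord count
    _shading_description(d)
    d.write_u32(n)                     # minimum resolution
    d.write_u32(n)                     # final maximum resolution
    _resource_description(d, quant)
    d.write_u32(0)                     # bone count
    decl = U3DBlock(C.BT_CLOD_MESH_DECL, d.finish())

    c = _begin(name)
    c.write_u32(nf)
    c.write_u32(n)
    c.write_u32(nn)
    c.write_u32(0)
    c.write_u32(0)
    c.write_u32(0)
    for x, y, z in resource.positions:
        c.write_f32(float(x)); c.write_f32(float(y)); c.write_f32(float(z))
    if normals is not None:
        for x, y, z in normals:
            c.write_f32(float(x)); c.write_f32(float(y)); c.write_f32(float(z))
    pos_ctx = C.static_context(n)
    nrm_ctx = C.static_context(nn) if nn else None
    for face in resource.faces:
        c.write_compressed_u32(C.CTX_SHADING_ID, 0)
        for v in face:
            c.write_compressed_u32(pos_ctx, int(v))
            if nrm_ctx is not None:
                c.write_compressed_u32(nrm_ctx, int(v))
    return decl, U3DBlock(C.BT_BASE_MESH_CONT, c.finish())


# ---------------------------------------------------------------------------
# appearance

def encode_shading_resources(material: Material, name: str
                             ) -> list[U3DBlock]:
    """One untextured lit shader + one material resource block.

    The shader enables alpha blending exactly when opacity < 1.
    """
    shader_name = f"{name}:shader"
    s = BitWriter()
    s.write_string(shader_name)
    s.write_u32(C.SHADER_ATTR_LIGHTING)
    s.write_f32(0.0)                             # alpha test reference
    s.write_u32(C.ALPHA_TEST_ALWAYS)
    s.write_u32(C.BLEND_ALPHA if material.opacity < 1.0 else C.BLEND_OPAQUE)
    s.write_u32(1)                               # render pass enables
    s.write_u32(0)                               # shader channels (no textures)
    s.write_u32(0)                               # alpha texture channels
    s.write_string(name)                         # material name
    shader = U3DBlock(C.BT_LIT_SHADER, s.finish())

    m = BitWriter()
    m.write_string(name)
    m.write_u32(C.MATERIAL_ATTR_ALL)
    for color in (material.ambient, material.diffuse, material.specular,
                  material.emissive):
        m.write_f32(color.r); m.write_f32(color.g); m.write_f32(color.b)
    m.write_f32(material.reflectivity)
    m.write_f32(material.opacity)
    return [shader, U3DBlock(C.BT_MATERIAL_RESOURCE, m.finish())]


# ---------------------------------------------------------------------------
# nodes and chains

def _chain(name: str, chain_type: int, inner: list[U3DBlock]) -> U3DBlock:
    w = BitWriter()
    w.write_string(name)
    w.write_u32(chain_type)
    w.write_u32(0)                     # chain attributes: no bounds
    head = len(name.encode("utf-8")) + 2 + 8
    for _ in range(-head % 4):         # padding so inner blocks stay aligned
        w.write_u8(0)
    w.write_u32(len(inner))
    data = w.finish() + serialize_blocks(inner)
    return U3DBlock(C.BT_MODIFIER_CHAIN, data)


def _group_node_block(name: str, parent: str, transform) -> U3DBlock:
    w = BitWriter()
    w.write_string(name)
    w.write_u32(1)                     # parent count
    w.write_string(parent)
    _write_matrix(w, transform)
    return U3DBlock(C.BT_GROUP_NODE, w.finish())


def _model_node_block(name: str, parent: str, transform,
                      resource_name: str) -> U3DBlock:
    w = BitWriter()
    w.write_string(name)
    w.write_u32(1)
    w.write_string(parent)
    _write_matrix(w, transform)
    w.write_string(resource_name)
    w.write_u32(C.MODEL_VISIBILITY_BOTH)
    return U3DBlock(C.BT_MODEL_NODE, w.finish())


def _shading_modifier_block(name: str, shader_name: str,
                            geometry) -> U3DBlock:
    if isinstance(geometry, MeshGeometry):
        attr = C.SHADING_ATTR_MESH
    elif isinstance(geometry, LineSetGeometry):
        attr = C.SHADING_ATTR_LINE
    else:
        attr = C.SHADING_ATTR_POINT
    w = _begin(name)                   # name + chain index
    w.write_u32(attr)
    w.write_u32(1)                     # shader list count
    w.write_u32(1)                     # shaders in list
    w.write_string(shader_name)
    return U3DBlock(C.BT_SHADING_MODIFIER, w.finish())


def encode_node_blocks(scene: Scene, config: EncoderConfig,
                       material_names: dict[tuple, str]) -> list[U3DBlock]:
    """One modifier chain per scene node, pre-order, parents linked by name."""
    root_name = config.root_node_name
    names: dict[str, SceneNode] = {}
    for node in scene.root.walk():
        disk_name = root_name if node is scene.root else node.name
        if disk_name in names:
            raise U3DEncodeError(
                f"duplicate node name {disk_name!r} on disk; node names "
                "must be unique across the tree for parent links")
        names[disk_name] = node

    out: list[U3DBlock] = []

    def emit(node: SceneNode, parent_name: str, disk_name: str) -> None:
        if node.kind == "group":
            out.append(_chain(disk_name, C.CHAIN_TYPE_NODE,
                              [_group_node_block(disk_name, parent_name,
                                                 node.transform)]))
            for child in node.children:
                emit(child, disk_name, child.name)
        else:
            geometry = scene.resources[node.geometry_ref]
            material = node.material or Material()
            mat_name = material_names[material.key()]
            inner = [
                _model_node_block(disk_name, parent_name, node.transform,
                                  node.geometry_ref),
                _shading_modifier_block(disk_name, f"{mat_name}:shader",
                                        geometry),
            ]
            out.append(_chain(disk_name, C.CHAIN_TYPE_NODE, inner))

    emit(scene.root, "", root_name)
    return out


def encode_light_view_defaults(config: EncoderConfig,
                               bounds: tuple[np.ndarray, np.ndarray] | None
                               ) -> list[U3DBlock]:
    """Optional default ambient light and/or a perspective view.

    The view camera sits on the +z axis at focus distance d from the
    bounding-box center and stores far clip = 10 d, so a reader can recover
    the framed target as ``position - (0, 0, far / 10)``. Both are off by
    default — PDF viewers supply their own defaults.
    """
    out: list[U3DBlock] = []
    if config.emit_default_lighting:
        r = BitWriter()
        r.write_string("DefaultAmbientLight")
        r.write_u32(C.LIGHT_ATTR_ENABLED)
        r.write_u8(C.LIGHT_TYPE_AMBIENT)
        for value in (1.0, 1.0, 1.0, 1.0):      # color rgba
            r.write_f32(value)
        for value in (1.0, 0.0, 0.0):           # attenuation constants
            r.write_f32(value)
        r.write_f32(180.0)                      # spot angle (unused)
        r.write_f32(1.0)                        # intensity
        out.append(U3DBlock(C.BT_LIGHT_RESOURCE, r.finish()))
        n = BitWriter()
        n.write_string("DefaultAmbientLight")
        n.write_u32(1)
        n.write_string(config.root_node_name)
        _write_matrix(n, _IDENTITY)
        n.write_string("DefaultAmbientLight")
        out.append(_chain("DefaultAmbientLight", C.CHAIN_TYPE_NODE,
                          [U3DBlock(C.BT_LIGHT_NODE, n.finish())]))
    if config.emit_default_view:
        center = np.zeros(3)
        radius = 1.0
        if bounds is not None:
            lo, hi = bounds
            center = (lo + hi) / 2.0
            radius = max(float(np.linalg.norm(hi - lo)) / 2.0, 1e-6)
        d = max(1.0, 2.5 * radius)
        r = BitWriter()
        r.write_string("DefaultView")
        r.write_u32(1)                          # render pass count
        r.write_string(config.root_node_name)   # pass root
        r.write_u32(0)                          # render attributes
        out.append(U3DBlock(C.BT_VIEW_RESOURCE, r.finish()))
        transform = _IDENTITY.copy()
        transform[:3, 3] = center + np.array([0.0, 0.0, d])
        n = BitWriter()
        n.write_string("DefaultView")
        n.write_u32(1)
        n.write_string(config.root_node_name)
        _write_matrix(n, transform)
        n.write_string("DefaultView")           # view resource name
        n.write_u32(0)                          # attributes: perspective
        n.write_f32(d / 100.0)                  # near clip
        n.write_f32(d * 10.0)                   # far clip
        n.write_f32(35.0)                       # projection fov (degrees)
        for value in (100.0, 100.0, 0.0, 0.0):  # viewport w/h/x/y
            n.write_f32(value)
        n.write_u32(0)                          # backdrop count
        n.write_u32(0)                          # overlay count
        out.append(_chain("DefaultView", C.CHAIN_TYPE_NODE,
                          [U3DBlock(C.BT_VIEW_NODE, n.finish())]))
    return out


def encode_header_block(declaration_size: int, file_size: int,
                        metadata) -> U3DBlock:
    """File-header block; its 32-bit type code reads 'U' '3' 'D' \\0."""
    w = BitWriter()
    w.write_u32(C.FILE_VERSION)
    w.write_u32(C.PROFILE_BASE)
    w.write_u32(declaration_size)
    w.write_u64(file_size)
    w.write_u32(C.CHAR_ENCODING_UTF8)
    return U3DBlock(C.BT_FILE_HEADER, w.finish(),
                    metadata=_metadata_bytes(list(metadata)))


# ---------------------------------------------------------------------------
# scene preparation + assembly

def _prepare_resource(rid: str, resource, config: EncoderConfig):
    issues = validate_geometry(resource)
    fatal = [i for i in issues if not i.droppable]
    if fatal:
        raise U3DEncodeError(
            f"geometry resource {rid!r} is invalid: "
            + "; ".join(i.message for i in fatal))
    droppable = [i for i in issues if i.droppable]
    if droppable:
        drop = {i.index for i in droppable}
        warnings.warn(
            f"resource {rid!r}: dropping {len(drop)} degenerate "
            "element(s) before export", U3DWarning, stacklevel=3)
        if isinstance(resource, MeshGeometry):
            keep = [i for i in range(len(resource.faces)) if i not in drop]
            resource = replace(resource, faces=resource.faces[keep])
        elif isinstance(resource, LineSetGeometry):
            keep = [i for i in range(len(resource.edges)) if i not in drop]
            resource = replace(resource, edges=resource.edges[keep])
    if (isinstance(resource, MeshGeometry) and config.include_normals
            and resource.normals is None):
        resource = compute_vertex_normals(resource)
    return resource


def _scene_bounds(scene: Scene):
    arrays = [r.positions for r in scene.resources.values()
              if len(r.positions)]
    if not arrays:
        return None
    allpos = np.vstack([a.astype(np.float64) for a in arrays])
    return allpos.min(axis=0), allpos.max(axis=0)


def write_file(scene: Scene, config: EncoderConfig | None = None) -> bytes:
    """Serialize a scene; raises before any bytes exist on failure."""
    config = config or EncoderConfig()
    for node in scene.model_nodes():
        if node.geometry_ref not in scene.resources:
            raise U3DEncodeError(
                f"model {node.name!r} references unknown geometry "
                f"{node.geometry_ref!r}")
    prepared = {rid: _prepare_resource(rid, res, config)
                for rid, res in scene.resources.items()}
    scene = Scene(root=scene.root, resources=prepared,
                  metadata=list(scene.metadata))

    # Deduplicate materials by value.
    material_names: dict[tuple, str] = {}
    materials: list[Material] = []
    for node in scene.model_nodes():
        mat = node.material or Material()
        if mat.key() not in material_names:
            material_names[mat.key()] = f"material_{len(materials)}"
            materials.append(mat)

    decl: list[U3DBlock] = []
    cont: list[U3DBlock] = []
    for rid, resource in scene.resources.items():
        if isinstance(resource, MeshGeometry):
            d, k = encode_mesh(resource, rid, config.quant,
                               include_normals=config.include_normals)
        elif isinstance(resource, LineSetGeometry):
            d, k = encode_line_set(resource, rid, config.quant)
        else:
            d, k = encode_point_set(resource, rid, config.quant)
        decl.append(_chain(rid, C.CHAIN_TYPE_MODEL_RESOURCE, [d]))
        cont.append(k)
    for mat in materials:
        decl.extend(encode_shading_resources(
            mat, material_names[mat.key()]))
    decl.extend(encode_light_view_defaults(config, _scene_bounds(scene)))
    decl.extend(encode_node_blocks(scene, config, material_names))

    metadata = list(config.creator_metadata) + list(scene.metadata)
    header = encode_header_block(0, 0, metadata)
    decl_bytes = serialize_blocks(decl)
    cont_bytes = serialize_blocks(cont)
    header_len = len(header.serialize())
    declaration_size = header_len + len(decl_bytes)
    file_size = declaration_size + len(cont_bytes)
    header = encode_header_block(declaration_size, file_size, metadata)
    return header.serialize() + decl_bytes + cont_bytes


def save_u3d(scene: Scene, path, config: EncoderConfig | None = None) -> int:
    """Write a scene to ``path``; returns the byte count."""
    data = write_file(scene, config)
    with open(path, "wb") as fh:
        fh.write(data)
    return len(data)
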