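"""Structural U3D parser/decoder for the block subset the encoder emits.

This reader exists as the round-trip oracle and the ``inspect`` backend,
not as a universal U3D importer: unknown block types are skipped using
their declared sizes, progressive mesh updates and textures are out of
scope. Blocks whose layouts use only uncompressed channels are parsed as
plain little-endian bytes; geometry continuation blocks are decoded with
the full bit codec, inverting the compression contexts exactly as written.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .bitio import BitReader
from .blocks import BlockSummary, U3DBlock, parse_blocks
from .errors import U3DParseError
from .scene import (ColorRGBA, LineSetGeometry, Material, MeshGeometry,
                    PointCloudGeometry, Scene, SceneNode)

__all__ = ["DecodedScene", "decode_scene", "summarize", "parse_blocks"]


class _Cursor:
    """Plain byte-level reader for uncompressed-only block layouts."""

    __slots__ = ("data", "pos")

    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def _take(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise U3DParseError("block data ends early", offset=self.pos)
        out = self.data[self.pos:self.pos + n]
        self.pos += n
        return out

    def u8(self) -> int:
        return self._take(1)[0]

    def u16(self) -> int:
        return int.from_bytes(self._take(2), "little")

    def u32(self) -> int:
        return int.from_bytes(self._take(4), "little")

    def u64(self) -> int:
        return int.from_bytes(self._take(8), "little")

    def f32(self) -> float:
        return struct.unpack("<f", self._take(4))[0]

    def string(self) -> str:
        return self._take(self.u16()).decode("utf-8")

    def skip(self, n: int) -> None:
        self._take(n)

    def matrix(self) -> np.ndarray:
        m = np.empty((4, 4), dtype=np.float64)
        for col in range(4):
            for row in range(4):
                m[row, col] = self.f32()
        return m


def _read_metadata(data: bytes) -> list[tuple[str, str]]:
    if not data:
        return []
    cur = _Cursor(data)
    count = cur.u32()
    pairs = []
    for _ in range(count):
        cur.u32()                      # attributes (string values only)
        pairs.append((cur.string(), cur.string()))
    return pairs


def _decode_point_cont(data: bytes, n_positions: int, iq: float
                       ) -> PointCloudGeometry:
    r = BitReader(data)
    r.read_string()
    r.read_u32()                       # chain index
    start, end = r.read_u32(), r.read_u32()
    if (start, end) != (0, n_positions):
        raise U3DParseError(
            f"point continuation resolution range ({start},{end}) "
            f"disagrees with declared {n_positions}")
    q = np.zeros((n_positions, 3), dtype=np.int64)
    prev = np.zeros(3, dtype=np.int64)
    for i in range(n_positions):
        r.read_compressed_u32(C.static_context(max(i, 1)))   # split index
        q[i] = prev + _read_diff(r)
        prev = q[i]
        if r.read_compressed_u32(C.CTX_NORMAL_COUNT):
            raise U3DParseError("point-set normals are not in this subset")
        for _ in range(r.read_compressed_u32(C.CTX_POINT_COUNT)):
            r.read_compressed_u32(C.CTX_SHADING_ID)
    return PointCloudGeometry(positions=(q * iq).astype(np.float32))


def _read_diff(r: BitReader) -> np.ndarray:
    signs = r.read_compressed_u8(C.CTX_POS_DIFF_SIGN)
    d = np.array([r.read_compressed_u32(C.CTX_POS_DIFF_X),
                  r.read_compressed_u32(C.CTX_POS_DIFF_Y),
                  r.read_compressed_u32(C.CTX_POS_DIFF_Z)], dtype=np.int64)
    for axis in range(3):
        if signs >> axis & 1:
            d[axis] = -d[axis]
    return d


def _decode_line_cont(data: bytes, n_positions: int, n_lines: int,
                      iq: float) -> LineSetGeometry:
    r = BitReader(data)
    r.read_string()
    r.read_u32()
    start, end = r.read_u32(), r.read_u32()
    if (start, end) != (0, n_positions):
        raise U3DParseError(
            f"line continuation resolution range ({start},{end}) "
            f"disagrees with declared {n_positions}")
    q = np.zeros((n_positions, 3), dtype=np.int64)
    prev = np.zeros(3, dtype=np.int64)
    edges: list[tuple[int, int]] = []
    for i in range(n_positions):
        r.read_compressed_u32(C.static_context(max(i, 1)))
        q[i] = prev + _read_diff(r)
        prev = q[i]
        if r.read_compressed_u32(C.CTX_NORMAL_COUNT):
            raise U3DParseError("line-set normals are not in this subset")
        for _ in range(r.read_compressed_u32(C.CTX_LINE_COUNT)):
            other = r.read_compressed_u32(C.static_context(i))
            r.read_compressed_u32(C.CTX_SHADING_ID)
            edges.append((other, i))
    if len(edges) != n_lines:
        raise U3DParseError(
            f"decoded {len(edges)} lines, declaration said {n_lines}")
    return LineSetGeometry(positions=(q * iq).astype(np.float32),
                           edges=np.asarray(edges, dtype=np.int64
                                            ).reshape(-1, 2))


def _decode_mesh_cont(data: bytes, decl: dict) -> MeshGeometry:
    r = BitReader(data)
    r.read_string()
    r.read_u32()
    nf, n, nn = r.read_u32(), r.read_u32(), r.read_u32()
    nd, ns, nt = r.read_u32(), r.read_u32(), r.read_u32()
    if (nf, n, nn) != (decl["faces"], decl["positions"], decl["normals"]):
        raise U3DParseError(
            "base-mesh continuation counts disagree with declaration")
    if (nd, ns, nt) != (0, 0, 0):
        raise U3DParseError("per-vertex colors/texcoords are not in this "
                            "subset")
    positions = np.empty((n, 3), dtype=np.float32)
    for i in range(n):
        positions[i] = [r.read_f32(), r.read_f32(), r.read_f32()]
    normals = None
    if nn:
        normals = np.empty((nn, 3), dtype=np.float32)
        for i in range(nn):
            normals[i] = [r.read_f32(), r.read_f32(), r.read_f32()]
    faces = np.empty((nf, 3), dtype=np.int64)
    pos_ctx = C.static_context(n)
    nrm_ctx = C.static_context(nn) if nn else None
    for i in range(nf):
        r.read_compressed_u32(C.CTX_SHADING_ID)
        for k in range(3):
            faces[i, k] = r.read_compressed_u32(pos_ctx)
            if nrm_ctx is not None:
                r.read_compressed_u32(nrm_ctx)
    return MeshGeometry(positions=positions, faces=faces, normals=normals)


@dataclass
class DecodedScene:
    """Decoded structural content of a U3D stream (this encoder's subset).

    ``position_tolerance`` maps resource ids to the per-axis inverse
    quantization bound (0 for meshes, whose coordinates travel as raw
    32-bit floats).
    """

    scene: Scene
    position_tolerance: dict[str, float] = field(default_factory=dict)
    alpha_blended_models: set[str] = field(default_factory=set)
    lights: list[str] = field(default_factory=list)
    views: list[dict] = field(default_factory=list)
    unknown_blocks: list[BlockSummary] = field(default_factory=list)
    declared_file_size: int = 0
    declaration_size: int = 0


def _flatten(blocks: list[BlockSummary]) -> list[BlockSummary]:
    """Expand modifier chains so every node/resource block is visible."""
    out: list[BlockSummary] = []
    for summary in blocks:
        out.append(summary)
        if summary.block_type == C.BT_MODIFIER_CHAIN:
            cur = _Cursor(summary.block.data)
            name = cur.string()
            cur.u32()                  # chain type
            cur.u32()                  # chain attributes
            cur.skip(-(len(name.encode("utf-8")) + 10) % 4)
            count = cur.u32()
            inner = parse_blocks(summary.block.data[cur.pos:],
                                 base_offset=summary.offset + 12 + cur.pos)
            if len(inner) != count:
                raise U3DParseError(
                    f"modifier chain {name!r} declares {count} modifiers, "
                    f"found {len(inner)}", offset=summary.offset)
            out.extend(inner)
    return out


def decode_scene(data: bytes) -> DecodedScene:
    """Reconstruct node tree, materials, metadata and geometry.

    Raises :class:`U3DParseError` on structural damage, including codec
    context desynchronization inside continuation blocks.
    """
    blocks = _flatten(parse_blocks(data))
    if blocks[0].block_type != C.BT_FILE_HEADER:
        raise U3DParseError("first block is not a file header", offset=0)

    head = _Cursor(blocks[0].block.data)
    head.u32()                          # version
    head.u32()                          # profile
    declaration_size = head.u32()
    declared_file_size = head.u64()
    head.u32()                          # character encoding
    metadata = _read_metadata(blocks[0].block.metadata)

    nodes: list[dict] = []              # parsed node blocks in file order
    decls: dict[str, dict] = {}
    conts: dict[str, U3DBlock] = {}
    shaders: dict[str, dict] = {}
    materials: dict[str, Material] = {}
    model_shaders: dict[str, str] = {}
    lights: list[str] = []
    views: list[dict] = []
    unknown: list[BlockSummary] = []

    for summary in blocks[1:]:
        bt = summary.block_type
        body = summary.block.data
        if bt in (C.BT_MODIFIER_CHAIN, C.BT_PRIORITY_UPDATE):
            continue
        if bt == C.BT_GROUP_NODE:
            cur = _Cursor(body)
            name = cur.string()
            if cur.u32() != 1:
                raise U3DParseError("multi-parent nodes not in subset",
                                    offset=summary.offset)
            nodes.append({"kind": "group", "name": name,
                          "parent": cur.string(),
                          "transform": cur.matrix()})
        elif bt == C.BT_MODEL_NODE:
            cur = _Cursor(body)
            name = cur.string()
            if cur.u32() != 1:
                raise U3DParseError("multi-parent nodes not in subset",
                                    offset=summary.offset)
            parent = cur.string()
            transform = cur.matrix()
            nodes.append({"kind": "model", "name": name, "parent": parent,
                          "transform": transform,
                          "resource": cur.string(),
                          "visibility": cur.u32()})
        elif bt == C.BT_LIGHT_NODE:
            cur = _Cursor(body)
            lights.append(cur.string())
        elif bt == C.BT_VIEW_NODE:
            cur = _Cursor(body)
            name = cur.string()
            cur.u32()
            cur.string()
            transform = cur.matrix()
            cur.string()                # view resource name
            cur.u32()                   # attributes
            near, far, fov = cur.f32(), cur.f32(), cur.f32()
            position = transform[:3, 3]
            views.append({"name": name, "position": position,
                          "near": near, "far": far, "fov": fov,
                          "target": position - np.array([0.0, 0.0,
                                                         far / 10.0])})
        elif bt == C.BT_SHADING_MODIFIER:
            cur = _Cursor(body)
            name = cur.string()
            cur.u32()                   # chain index
            cur.u32()                   # attributes
            if cur.u32() != 1 or cur.u32() != 1:
                raise U3DParseError("multi-shader lists not in subset",
                                    offset=summary.offset)
            model_shaders[name] = cur.string()
        elif bt == C.BT_LIT_SHADER:
            cur = _Cursor(body)
            name = cur.string()
            cur.u32()                   # shader attributes
            cur.f32()                   # alpha test reference
            cur.u32()                   # alpha test function
            blend = cur.u32()
            cur.u32()                   # render pass enables
            cur.u32()
            cur.u32()
            shaders[name] = {"material": cur.string(),
                             "alpha_blend": blend == C.BLEND_ALPHA}
        elif bt == C.BT_MATERIAL_RESOURCE:
            cur = _Cursor(body)
            name = cur.string()
            cur.u32()                   # attribute mask (always full here)
            cols = [ColorRGBA(cur.f32(), cur.f32(), cur.f32())
                    for _ in range(4)]
            materials[name] = Material(
                ambient=cols[0], diffuse=cols[1], specular=cols[2],
                emissive=cols[3], reflectivity=cur.f32(), opacity=cur.f32())
        elif bt == C.BT_LIGHT_RESOURCE:
            pass
        elif bt == C.BT_VIEW_RESOURCE:
            pass
        elif bt in (C.BT_POINT_SET_DECL, C.BT_LINE_SET_DECL):
            cur = _Cursor(body)
            name = cur.string()
            cur.u32()                   # chain index
            cur.u32()                   # reserved
            count = cur.u32()
            n_pos = cur.u32()
            for _ in range(4):
                cur.u32()
            for _ in range(4):          # shading description
                cur.u32()
            for _ in range(3):          # quality factors
                cur.u32()
            pos_iq = cur.f32()
            decls[name] = {
                "kind": "pointset" if bt == C.BT_POINT_SET_DECL
                else "lineset",
                "count": count, "positions": n_pos, "pos_iq": pos_iq}
        elif bt == C.BT_CLOD_MESH_DECL:
            cur = _Cursor(body)
            name = cur.string()
            cur.u32()                   # chain index
            attrs = cur.u32()
            nf = cur.u32()
            n_pos = cur.u32()
            nn = cur.u32()
            for _ in range(3):
                cur.u32()
            for _ in range(4):          # shading description
                cur.u32()
            min_res, max_res = cur.u32(), cur.u32()
            if min_res != max_res:
                raise U3DParseError(
                    "progressive meshes (min != max resolution) are not in "
                    "this subset", offset=summary.offset)
            for _ in range(3):
                cur.u32()
            pos_iq = cur.f32()
            decls[name] = {"kind": "mesh", "faces": nf, "positions": n_pos,
                           "normals": nn, "attributes": attrs,
                           "pos_iq": pos_iq}
        elif bt in (C.BT_POINT_SET_CONT, C.BT_LINE_SET_CONT,
                    C.BT_BASE_MESH_CONT):
            cur = _Cursor(body)
            conts[cur.string()] = summary.block
        else:
            unknown.append(summary)

    # Geometry resources
    scene = Scene(root=SceneNode(kind="group", name="<pending>"))
    scene.metadata = metadata
    tolerance: dict[str, float] = {}
    for name, decl in decls.items():
        cont = conts.get(name)
        if cont is None:
            raise U3DParseError(
                f"declaration {name!r} has no continuation block")
        try:
            if decl["kind"] == "pointset":
                res = _decode_point_cont(cont.data, decl["positions"],
                                         decl["pos_iq"])
                tolerance[name] = 0.5 * decl["pos_iq"]
            elif decl["kind"] == "lineset":
                res = _decode_line_cont(cont.data, decl["positions"],
                                        decl["count"], decl["pos_iq"])
                tolerance[name] = 0.5 * decl["pos_iq"]
            else:
                res = _decode_mesh_cont(cont.data, decl)
                tolerance[name] = 0.0
        except U3DParseError as exc:
            raise U3DParseError(
                f"while decoding continuation of {name!r}: {exc}") from exc
        scene.resources[name] = res

    # Node tree
    by_name: dict[str, SceneNode] = {}
    root = None
    for info in nodes:
        node = SceneNode(kind=info["kind"], name=info["name"],
                         transform=info["transform"].astype(np.float32))
        by_name[info["name"]] = node
        if info["kind"] == "model":
            node.geometry_ref = info["resource"]
        if info["parent"] == "":
            if root is not None:
                raise U3DParseError("multiple root nodes")
            if info["kind"] != "group":
                raise U3DParseError("root node is not a group")
            root = node
    if root is None:
        raise U3DParseError("no root node (parent name \"\") found")
    for info in nodes:
        if info["parent"] == "":
            continue
        parent = by_name.get(info["parent"])
        if parent is None:
            raise U3DParseError(
                f"node {info['name']!r} links to unknown parent "
                f"{info['parent']!r}")
        parent.children.append(by_name[info["name"]])
    scene.root = root

    # Materials onto model nodes
    alpha_models: set[str] = set()
    for model_name, shader_name in model_shaders.items():
        node = by_name.get(model_name)
        shader = shaders.get(shader_name)
        if node is None or shader is None:
            raise U3DParseError(
                f"shading modifier {model_name!r} references unknown "
                "model or shader")
        node.material = materials.get(shader["material"])
        if shader["alpha_blend"]:
            alpha_models.add(model_name)

    for node in scene.model_nodes():
        if node.geometry_ref not in scene.resources:
            raise U3DParseError(
                f"model {node.name!r} references undeclared geometry "
                f"{node.geometry_ref!r}")

    return DecodedScene(scene=scene, position_tolerance=tolerance,
                        alpha_blended_models=alpha_models,
                        lights=lights, views=views, unknown_blocks=unknown,
                        declared_file_size=declared_file_size,
                        declaration_size=declaration_size)


def summarize(data: bytes) -> dict:
    """Counts per block kind and per-geometry totals, as a JSON-able dict."""
    decoded = decode_scene(data)
    blocks = _flatten(parse_blocks(data))
    kind_counts: dict[str, int] = {}
    for summary in blocks:
        kind_counts[summary.kind] = kind_counts.get(summary.kind, 0) + 1
    scene = decoded.scene
    geom = {"point_sets": 0, "line_sets": 0, "meshes": 0}
    totals = {"points": 0, "lines": 0, "faces": 0}
    for res in scene.resources.values():
        if isinstance(res, MeshGeometry):
            geom["meshes"] += 1
            totals["faces"] += len(res.faces)
        elif isinstance(res, LineSetGeometry):
            geom["line_sets"] += 1
            totals["lines"] += len(res.edges)
        else:
            geom["point_sets"] += 1
            totals["points"] += len(res.positions)
    n_groups = sum(1 for n in scene.root.walk() if n.kind == "group")
    material_count = len({n.material.key() for n in scene.model_nodes()
                          if n.material is not None})
    return {
        "file_size": len(data),
        "declared_file_size": decoded.declared_file_size,
        "declaration_size": decoded.declaration_size,
        "block_counts": dict(sorted(kind_counts.items())),
        "model_nodes": len(scene.model_nodes()),
        "group_nodes": n_groups,
        "geometry_resources": geom,
        "totals": totals,
        "materials": material_count,
        "lights": len(decoded.lights),
        "views": len(decoded.views),
        "metadata": [list(pair) for pair in scene.metadata],
    }
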