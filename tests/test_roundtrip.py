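"""Encoder -> reader round-trip fidelity and structural file properties."""

import numpy as np
import pytest

from u3dkit import (EncoderConfig, LineSetGeometry, MeshGeometry, ObjectSpec,
                    PointCloudGeometry, QuantizationParams, Scene,
                    U3DEncodeError, U3DParseError, U3DWarning, add_model,
                    apply_defaults, decode_scene, make_fixture, parse_blocks,
                    summarize, write_file)
from u3dkit.constants import (BT_CLOD_MESH_DECL, BT_FILE_HEADER,
                              MESH_ATTR_EXCLUDE_NORMALS)
from u3dkit.fixtures import FIXTURE_KINDS, random_scene
from conftest import build_scene

KIND_TYPE = {"grid_points": "pointset", "helix_line": "lineset",
             "cube_mesh": "mesh", "sphere_mesh": "mesh"}


def edge_multiset(edges):
    return sorted(tuple(sorted(map(int, e))) for e in edges)


def assert_geometry_equal(decoded, original, tolerance):
    assert len(decoded.positions) == len(original.positions)
    if isinstance(original, MeshGeometry):
        assert np.array_equal(decoded.positions, original.positions)
        assert np.array_equal(decoded.faces, original.faces)
    else:
        # decoded coordinates live in a 32-bit float container, so allow
        # half-ulp representation slack on top of the quantization bound
        err = np.abs(decoded.positions.astype(np.float64)
                     - original.positions.astype(np.float64)).max()
        assert err <= tolerance + 1e-6
        if isinstance(original, LineSetGeometry):
            assert edge_multiset(decoded.edges) == edge_multiset(
                original.edges)


def tree_shape(node, parent=""):
    out = [(node.name, node.kind, parent)]
    for child in node.children:
        out.extend(tree_shape(child, node.name))
    return out


@pytest.mark.parametrize("kind", FIXTURE_KINDS)
@pytest.mark.parametrize("n_objects", [1, 2])
@pytest.mark.parametrize("shared", [True, False])
def test_fixture_matrix_round_trip(kind, n_objects, shared):
    """Node tree, metadata, topology and counts survive; mesh coordinates
    bit-exactly, quantized point/line coordinates within 0.5/factor."""
    geometry = make_fixture(kind)
    objects = []
    for i in range(n_objects):
        rid = "shape" if shared else f"shape_{i}"
        objects.append((KIND_TYPE[kind], rid, geometry,
                        {"name": f"obj_{i}", "group_path": "G"}))
    scene = build_scene(objects, metadata=[("Title", kind)])
    data = write_file(scene)
    decoded = decode_scene(data)

    assert tree_shape(decoded.scene.root) == tree_shape(scene.root)
    assert decoded.scene.metadata == scene.metadata
    assert len(decoded.scene.resources) == (1 if shared else n_objects)
    for rid, resource in scene.resources.items():
        assert_geometry_equal(decoded.scene.resources[rid], resource,
                              decoded.position_tolerance[rid])


def test_quantization_tolerance_bound(grid):
    factor = 50.0
    scene = build_scene([("pointset", "g", grid, {"name": "p"})])
    data = write_file(scene, EncoderConfig(
        quant=QuantizationParams(position=factor)))
    decoded = decode_scene(data)
    assert decoded.position_tolerance["g"] == pytest.approx(0.5 / factor)
    err = np.abs(decoded.scene.resources["g"].positions
                 - grid.positions).max()
    assert err <= 0.5 / factor


def test_single_point_at_origin_exact():
    scene = build_scene([("pointset", "p",
                          PointCloudGeometry(positions=[(0, 0, 0)]),
                          {"name": "origin"})])
    decoded = decode_scene(write_file(scene))
    assert decoded.scene.resources["p"].positions.tolist() == [[0, 0, 0]]


def test_ten_thousand_random_points_order_preserved():
    rng = np.random.default_rng(3)
    cloud = PointCloudGeometry(positions=rng.uniform(-5, 5, (10_000, 3)))
    scene = build_scene([("pointset", "c", cloud, {"name": "cloud"})])
    decoded = decode_scene(write_file(scene))
    got = decoded.scene.resources["c"]
    assert len(got.positions) == 10_000
    assert np.abs(got.positions - cloud.positions).max() <= 5e-4 + 1e-6


def test_helix_chain_topology(helix):
    scene = build_scene([("lineset", "h", helix, {"name": "vcg"})])
    decoded = decode_scene(write_file(scene))
    got = decoded.scene.resources["h"]
    assert len(got.edges) == 99
    # chain topology: every consecutive pair joined exactly once
    assert edge_multiset(got.edges) == [(i, i + 1) for i in range(99)]


def test_two_points_one_edge():
    lines = LineSetGeometry(positions=[(0, 0, 0), (1, 1, 1)],
                            edges=[(0, 1)])
    scene = build_scene([("lineset", "l", lines, {"name": "seg"})])
    decoded = decode_scene(write_file(scene))
    got = decoded.scene.resources["l"]
    assert got.edges.tolist() == [[0, 1]]
    assert np.abs(got.positions
                  - lines.positions).max() <= 5e-4


def test_edgeless_line_set_parses():
    lines = LineSetGeometry(positions=[(0, 0, 0), (1, 0, 0)], edges=[])
    scene = build_scene([("lineset", "l", lines, {"name": "bare"})])
    decoded = decode_scene(write_file(scene))
    assert len(decoded.scene.resources["l"].edges) == 0


def test_degenerate_elements_dropped_with_warning():
    lines = LineSetGeometry(positions=[(0, 0, 0), (1, 0, 0)],
                            edges=[(0, 1), (1, 1)])
    scene = build_scene([("lineset", "l", lines, {"name": "x"})])
    with pytest.warns(U3DWarning, match="degenerate"):
        decoded = decode_scene(write_file(scene))
    assert decoded.scene.resources["l"].edges.tolist() == [[0, 1]]


def test_opacity_decodes_with_blending(mixed_file):
    decoded = decode_scene(mixed_file)
    node = [n for n in decoded.scene.model_nodes()
            if n.name == "trajectory"][0]
    assert node.material.opacity == pytest.approx(0.5)
    assert node.material.diffuse.rgb() == (1.0, 0.0, 0.0)
    assert "trajectory" in decoded.alpha_blended_models
    assert "box" not in decoded.alpha_blended_models


def test_mixed_scene_summary(mixed_file):
    report = summarize(mixed_file)
    assert report["model_nodes"] == 3
    geom = report["geometry_resources"]
    assert (geom["point_sets"], geom["line_sets"], geom["meshes"]) == (1, 1, 1)
    assert report["metadata"] == [["Title", "mixed scene"]]


def test_shared_geometry_single_declaration(cube):
    scene = build_scene([("mesh", "cube", cube, {"name": f"m{i}"})
                         for i in range(3)])
    data = write_file(scene)
    decl_count = sum(
        1 for b in parse_blocks(data) for inner
        in ([b] if b.block_type != 0xFFFFFF14 else [])
        if b.block_type == BT_CLOD_MESH_DECL)
    report = summarize(data)
    assert report["model_nodes"] == 3
    assert report["geometry_resources"]["meshes"] == 1
    assert report["block_counts"]["mesh declaration"] == 1
    assert report["block_counts"]["mesh continuation"] == 1


def test_shared_resource_file_strictly_smaller():
    """Three models on one 500-vertex mesh vs three duplicated resources."""
    mesh = make_fixture("sphere_mesh", {"subdivisions": 3})  # 642 vertices
    big = MeshGeometry(positions=mesh.positions[:500],
                       faces=mesh.faces[(mesh.faces < 500).all(axis=1)],
                       normals=mesh.normals[:500])
    shared = build_scene([("mesh", "m", big, {"name": f"o{i}"})
                          for i in range(3)])
    duplicated = build_scene([("mesh", f"m{i}", big, {"name": f"o{i}"})
                              for i in range(3)])
    assert len(write_file(shared)) < len(write_file(duplicated))


def test_determinism_byte_identical(mixed_scene):
    assert write_file(mixed_scene) == write_file(mixed_scene)


def test_header_magic_and_declared_sizes(mixed_file):
    assert mixed_file[:3] == b"\x55\x33\x44"
    decoded = decode_scene(mixed_file)
    assert decoded.declared_file_size == len(mixed_file)
    blocks = parse_blocks(mixed_file)
    assert blocks[0].block_type == BT_FILE_HEADER
    # declaration size points at the continuation section boundary
    boundary = decoded.declaration_size
    assert boundary % 4 == 0
    kinds_after = {b.kind for b in blocks if b.offset >= boundary}
    assert kinds_after <= {"point set continuation", "line set continuation",
                           "mesh continuation"}
    assert kinds_after


def test_empty_scene_round_trips():
    data = write_file(Scene())
    decoded = decode_scene(data)
    assert decoded.scene.model_nodes() == []
    assert summarize(data)["model_nodes"] == 0


def test_normals_excluded_attribute(cube):
    scene = build_scene([("mesh", "c", cube, {"name": "m"})])
    config = EncoderConfig(include_normals=False)
    data = write_file(scene, config)
    decoded = decode_scene(data)
    mesh = decoded.scene.resources["c"]
    assert mesh.normals is None
    decl = [b for b in parse_blocks(data)]
    # attribute flag visible in the declaration block (inside its chain)
    from u3dkit.reader import _flatten
    decls = [b for b in _flatten(parse_blocks(data))
             if b.block_type == BT_CLOD_MESH_DECL]
    assert len(decls) == 1
    # attribute word sits right after name + chain index
    body = decls[0].block.data
    name_len = int.from_bytes(body[:2], "little")
    attr_off = 2 + name_len + 4
    attrs = int.from_bytes(body[attr_off:attr_off + 4], "little")
    assert attrs & MESH_ATTR_EXCLUDE_NORMALS


def test_unresolvable_reference_fails_before_output(grid):
    scene = Scene()
    scene.add_resource("g", grid)
    node = add_model(scene, apply_defaults(
        ObjectSpec("pointset", "g", name="p")), "g")
    node.geometry_ref = "gone"      # corrupt after validation
    with pytest.raises(U3DEncodeError, match="gone"):
        write_file(scene)


def test_empty_point_resource_rejected():
    scene = Scene()
    scene.add_resource("empty", PointCloudGeometry(
        positions=np.zeros((0, 3))))
    with pytest.raises(U3DEncodeError, match="no positions"):
        write_file(scene)


def test_duplicate_disk_names_rejected(grid):
    scene = build_scene([
        ("pointset", "g", grid, {"name": "same", "group_path": "A"}),
        ("pointset", "g", grid, {"name": "same", "group_path": "B"}),
    ])
    with pytest.raises(U3DEncodeError, match="unique"):
        write_file(scene)


def test_light_and_view_emission(grid):
    scene = build_scene([("pointset", "g", grid, {"name": "p"})])
    off = summarize(write_file(scene))
    assert off["lights"] == 0 and off["views"] == 0
    config = EncoderConfig(emit_default_lighting=True, emit_default_view=True)
    data = write_file(scene, config)
    on = summarize(data)
    assert on["lights"] == 1 and on["views"] == 1
    decoded = decode_scene(data)
    center = (grid.positions.min(axis=0) + grid.positions.max(axis=0)) / 2
    assert np.allclose(decoded.views[0]["target"], center, atol=1e-5)


def test_truncated_file_reports_offset(mixed_file):
    with pytest.raises(U3DParseError):
        decode_scene(mixed_file[:len(mixed_file) - 2])


def test_random_scenes_round_trip():
    for seed in range(25):
        scene = random_scene(seed)
        data = write_file(scene)
        decoded = decode_scene(data)
        assert tree_shape(decoded.scene.root) == tree_shape(scene.root)
        assert decoded.scene.metadata == scene.metadata
        for rid, resource in scene.resources.items():
            assert_geometry_equal(decoded.scene.resources[rid], resource,
                                  decoded.position_tolerance[rid])
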