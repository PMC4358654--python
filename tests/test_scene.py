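"""Scene-graph construction, normal computation and geometry validation."""

import numpy as np
import pytest

from u3dkit import (LineSetGeometry, MeshGeometry, ObjectSpec, Scene,
                    U3DStructureError, U3DWarning, add_group_path, add_model,
                    apply_defaults, compute_vertex_normals, make_fixture,
                    validate_geometry)


def spec(**kwargs):
    base = dict(object_type="pointset", geometry_id="g")
    base.update(kwargs)
    return apply_defaults(ObjectSpec(**base))


class TestGroupPath:
    def test_creates_intermediate_groups(self):
        scene = Scene()
        node = add_group_path(scene, "A/B")
        assert node.name == "B"
        assert [n.name for n in scene.root.walk()] == ["Scene", "A", "B"]

    def test_idempotent(self):
        scene = Scene()
        first = add_group_path(scene, "A/B")
        before = sum(1 for _ in scene.root.walk())
        again = add_group_path(scene, "A/B")
        assert again is first
        assert sum(1 for _ in scene.root.walk()) == before

    def test_empty_path_rejected(self):
        with pytest.raises(U3DStructureError):
            add_group_path(Scene(), "")

    def test_root_path_returns_root(self):
        scene = Scene()
        assert add_group_path(scene, "/") is scene.root

    def test_model_collision_rejected(self, grid):
        scene = Scene()
        scene.add_resource("g", grid)
        add_model(scene, spec(name="A"), "g")
        with pytest.raises(U3DStructureError):
            add_group_path(scene, "A/B")


class TestAddModel:
    def test_shared_geometry_keeps_one_resource(self, grid):
        scene = Scene()
        scene.add_resource("g", grid)
        add_model(scene, spec(name="first"), "g")
        add_model(scene, spec(name="second"), "g")
        assert len(scene.resources) == 1
        assert len(scene.model_nodes()) == 2

    def test_root_path_model_is_root_child(self, grid):
        scene = Scene()
        scene.add_resource("g", grid)
        node = add_model(scene, spec(name="m", group_path="/"), "g")
        assert node in scene.root.children

    def test_dangling_geometry_ref(self, grid):
        scene = Scene()
        with pytest.raises(U3DStructureError):
            add_model(scene, spec(name="m"), "missing")

    def test_sibling_clash_autosuffixes_with_warning(self, grid):
        scene = Scene()
        scene.add_resource("g", grid)
        add_model(scene, spec(name="m"), "g")
        with pytest.warns(U3DWarning, match="renamed"):
            node = add_model(scene, spec(name="m"), "g")
        assert node.name == "m_2"

    def test_material_built_from_spec(self, grid):
        scene = Scene()
        scene.add_resource("g", grid)
        node = add_model(scene, spec(name="m", diffuse=(1.0, 0.0, 0.0),
                                     opacity=0.25), "g")
        assert node.material.diffuse.rgb() == (1.0, 0.0, 0.0)
        assert node.material.opacity == 0.25
        assert node.material.ambient.r == pytest.approx(0.1)


class TestVertexNormals:
    def test_ccw_triangle_points_up(self):
        mesh = MeshGeometry(positions=[(0, 0, 0), (1, 0, 0), (0, 1, 0)],
                            faces=[(0, 1, 2)])
        out = compute_vertex_normals(mesh)
        assert np.allclose(out.normals, [(0, 0, 1)] * 3)

    def test_reversed_winding_points_down(self):
        mesh = MeshGeometry(positions=[(0, 0, 0), (1, 0, 0), (0, 1, 0)],
                            faces=[(0, 2, 1)])
        out = compute_vertex_normals(mesh)
        assert np.allclose(out.normals, [(0, 0, -1)] * 3)

    def test_three_orthogonal_faces_average(self):
        # Vertex 0 shared by three mutually orthogonal equal-area right
        # triangles whose outward normals are +x, +y, +z; the area-weighted
        # average is (1,1,1)/sqrt(3). Expected value computed by the
        # brute-force oracle below and frozen here.
        positions = [(0, 0, 0),
                     (0, 1, 0), (0, 0, 1),     # face in x=0 plane -> +x
                     (0, 0, 1), (1, 0, 0),     # face in y=0 plane -> +y
                     (1, 0, 0), (0, 1, 0)]     # face in z=0 plane -> +z
        faces = [(0, 1, 2), (0, 3, 4), (0, 5, 6)]
        out = compute_vertex_normals(MeshGeometry(positions=positions,
                                                  faces=faces))
        # independent oracle: accumulate area-weighted face normals
        pos = np.asarray(positions, dtype=float)
        acc = np.zeros(3)
        for a, b, c in faces:
            acc += np.cross(pos[b] - pos[a], pos[c] - pos[a]) / 2.0
        expected = acc / np.linalg.norm(acc)
        assert np.allclose(expected, np.ones(3) / np.sqrt(3))
        assert np.allclose(out.normals[0], expected, atol=1e-6)

    def test_degenerate_incidence_fallback(self):
        mesh = MeshGeometry(positions=[(0, 0, 0), (1, 0, 0), (2, 0, 0)],
                            faces=[(0, 1, 2)])    # collinear: zero area
        with pytest.warns(U3DWarning, match="fallback"):
            out = compute_vertex_normals(mesh)
        assert np.allclose(out.normals, [(0, 0, 1)] * 3)

    def test_existing_normals_preserved(self, cube):
        before = cube.normals.copy()
        out = compute_vertex_normals(cube)
        assert np.array_equal(out.normals, before)

    @pytest.mark.parametrize("kind", ["cube_mesh", "sphere_mesh"])
    def test_unit_length(self, kind):
        mesh = make_fixture(kind)
        lens = np.linalg.norm(mesh.normals.astype(np.float64), axis=1)
        assert np.all(np.abs(lens - 1.0) < 1e-6)


class TestValidateGeometry:
    def test_degenerate_face_reported_droppable(self):
        mesh = MeshGeometry(positions=np.zeros((3, 3)), faces=[(0, 1, 1)])
        issues = validate_geometry(mesh)
        assert [i.code for i in issues] == ["degenerate_face"]
        assert issues[0].droppable

    def test_edge_out_of_range(self):
        lines = LineSetGeometry(positions=np.zeros((3, 3)), edges=[(0, 5)])
        issues = validate_geometry(lines)
        assert [i.code for i in issues] == ["index_out_of_range"]
        assert not issues[0].droppable

    def test_valid_cube_is_clean(self, cube):
        assert validate_geometry(cube) == []

    def test_cube_is_closed(self, cube):
        # every undirected edge shared by exactly two faces
        from collections import Counter
        edges = Counter()
        for a, b, c in cube.faces:
            for e in ((a, b), (b, c), (c, a)):
                edges[tuple(sorted(e))] += 1
        assert len(cube.positions) == 8 and len(cube.faces) == 12
        assert set(edges.values()) == {2}
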