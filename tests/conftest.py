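import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from u3dkit import (ObjectSpec, Scene, add_model, apply_defaults, make_fixture,
                    write_file)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def cube():
    return make_fixture("cube_mesh")


@pytest.fixture
def sphere():
    return make_fixture("sphere_mesh")


@pytest.fixture
def helix():
    return make_fixture("helix_line")


@pytest.fixture
def grid():
    return make_fixture("grid_points")


def build_scene(objects, metadata=()):
    """objects: list of (object_type, resource_id, geometry, spec_kwargs)."""
    scene = Scene()
    for otype, rid, geometry, kwargs in objects:
        if rid not in scene.resources:
            scene.add_resource(rid, geometry)
        spec = apply_defaults(
            ObjectSpec(object_type=otype, geometry_id=rid, **kwargs))
        add_model(scene, spec, rid)
    scene.metadata.extend(metadata)
    return scene


@pytest.fixture
def mixed_scene(grid, helix, cube):
    return build_scene([
        ("pointset", "grid", grid, {"name": "points", "group_path": "A"}),
        ("lineset", "helix", helix, {"name": "trajectory",
                                     "diffuse": (1.0, 0.0, 0.0),
                                     "opacity": 0.5}),
        ("mesh", "cube", cube, {"name": "box", "group_path": "A/B"}),
    ], metadata=[("Title", "mixed scene")])


@pytest.fixture
def mixed_file(mixed_scene):
    return write_file(mixed_scene)
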