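"""Build the all-three-kinds demo scene used for the manual PDF check.

One point cloud, one polyline and one mesh, grouped under a common root,
with metadata and a transparent object — everything the manual
Adobe-Reader inspection (docs/pdf_embedding.md) needs to exercise.
"""

from pathlib import Path

from u3dkit import (ObjectSpec, Scene, add_model, apply_defaults,
                    make_fixture, save_u3d, summarize)

out_dir = Path(__file__).resolve().parent.parent / "scratch"
out_dir.mkdir(exist_ok=True)
out = out_dir / "mixed.u3d"

scene = Scene()
scene.add_resource("markers", make_fixture("grid_points", {"nx": 2, "ny": 2,
                                                           "nz": 2}))
scene.add_resource("track", make_fixture("helix_line"))
scene.add_resource("body", make_fixture("sphere_mesh"))

for otype, rid, name, kwargs in [
    ("pointset", "markers", "Markers", {"diffuse": (0.1, 0.1, 0.9)}),
    ("lineset", "track", "Track", {"diffuse": (0.9, 0.1, 0.1)}),
    ("mesh", "body", "Body", {"diffuse": (0.8, 0.8, 0.5), "opacity": 0.5}),
]:
    add_model(scene, apply_defaults(ObjectSpec(
        object_type=otype, geometry_id=rid, name=name,
        group_path="Demo", **kwargs)), rid)
scene.metadata.append(("Title", "u3dkit mixed demo"))

size = save_u3d(scene, out)
report = summarize(out.read_bytes())
print(f"wrote {out} ({size} bytes)")
geom = report["geometry_resources"]
print(f"{geom['point_sets']} point set, {geom['line_sets']} line set, "
      f"{geom['meshes']} mesh; {report['model_nodes']} model nodes under "
      f"group 'Demo'")
# Embed scratch/mixed.u3d into a PDF per docs/pdf_embedding.md to confirm
# the scene renders in Adobe Reader.
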