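"""Export a 3D trajectory (e.g. a vectorcardiogram loop) as a line set.

A vectorcardiogram is the trajectory of the heart's electrical vector over
time — inherently 3D data that flat projections cripple. Here a synthetic
closed loop stands in for one heartbeat; the connection list is omitted and
the automatic rule joins each sample to the next.
"""

from pathlib import Path

import numpy as np

from u3dkit import (LineSetGeometry, ObjectSpec, Scene, add_model,
                    apply_defaults, auto_connect, save_u3d, summarize)

out_dir = Path(__file__).resolve().parent.parent / "scratch"
out_dir.mkdir(exist_ok=True)
out = out_dir / "trajectory.u3d"

# Synthetic cardiac-style loop: a twisted closed curve, 200 samples.
t = np.linspace(0.0, 2.0 * np.pi, 200)
loop = np.column_stack([np.sin(t) * (1.0 + 0.3 * np.cos(3 * t)),
                        np.cos(t) * (1.0 + 0.3 * np.cos(3 * t)),
                        0.4 * np.sin(3 * t)])

lines = LineSetGeometry(positions=loop, edges=auto_connect(len(loop)))
scene = Scene()
scene.add_resource("loop", lines)
add_model(scene,
          apply_defaults(ObjectSpec(object_type="lineset",
                                    geometry_id="loop",
                                    name="Loop",
                                    diffuse=(0.8, 0.1, 0.1))),
          "loop")
scene.metadata.append(("Description", "synthetic trajectory loop"))
size = save_u3d(scene, out)

report = summarize(out.read_bytes())
print(f"wrote {out} ({size} bytes)")
print(f"positions: 200, decoded segments: {report['totals']['lines']}")
# 199 segments = 200 samples chained node-to-next by the automatic rule.
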