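# u3dkit

Export point clouds, line sets (polylines) and triangle meshes to
**Universal 3D (U3D, ECMA-363)** — the format PDF 3D annotations embed —
without leaving Python or the shell.

## Why

Scientific data is often intrinsically 3D: particle or marker
distributions, trajectories such as vectorcardiogram loops or fiber
tracks, segmented anatomical surfaces. A PDF can carry an *interactive*
3D model of such data, letting the reader orbit and zoom instead of
squinting at one fixed 2.5D projection — but producing the required U3D
stream is the bottleneck. Mainstream mesh tools neglect exactly the
geometry kinds scientists need most (bare point clouds and polylines), and
the reference tooling demands programming against a C++ API.

`u3dkit` is a small conversion tool plus library for that gap: CSV-like
tables, OBJ/PLY meshes or programmatically built geometry go in; a single
self-contained `.u3d` file comes out, ready for `media9`/LaTeX, iText or
any other PDF authoring route. Scenes support hierarchical object trees,
geometry resources shared by multiple objects, per-object color and
transparency, and file-level metadata. A structural reader decodes
everything the encoder emits and doubles as the round-trip oracle of the
test suite.

## The format, briefly

A U3D file is a sequence of typed, 32-bit-aligned binary **blocks**:
declaration blocks announce nodes and resources, continuation blocks carry
bulk geometry. Block payloads are bit streams produced by an adaptive
arithmetic coder with three channel families: uncompressed primitives
(u8/u16/u32/u64/f32/strings), *static* contexts (uniform over a known
range, used e.g. for face indices), and *dynamic* contexts (adaptive
histograms with an escape symbol, used for quantized coordinate
differences). Point/line coordinates are quantized as
`q = round(x · f)` with factor `f` (default 1000), so decoded positions
satisfy

&nbsp;&nbsp;&nbsp;&nbsp;|x − q / f| ≤ 0.5 / f  per axis (5·10⁻⁴ by default),

while mesh coordinates travel as raw 32-bit floats and decode bit-exactly.
Meshes are written as single full-resolution base meshes (a
continuous-level-of-detail mesh with minimum = maximum resolution), which
is what final-figure export needs. See `docs/methods.md` for the emitted
block subset and every numeric choice.

## Worked example

```sh
$ printf '0,0,0\n1,0,0\n2,0,0\n3,1,1\n' > p.csv
$ u3dkit convert --points p.csv -o out.u3d
INFO object p: pointset, 4 points
INFO wrote out.u3d (704 bytes, 1 objects)
$ u3dkit inspect out.u3d
out.u3d: 704 bytes (declared 704)
  model nodes: 1   group nodes: 1   materials: 1
  geometry: 1 point set(s) [4 pts], 0 line set(s) [0 segs], 0 mesh(es) [0 faces]
  ...
```

The four CSV rows became one point-set object with an auto-generated
specification (name from the file stem); the declared size in the header
equals the actual byte count, and `inspect` decodes the same counts that
went in. The same command takes `--lines` (edges auto-chained
node-to-next when no `--line-connections` file is given, n points → n−1
segments), `--mesh` for OBJ/ASCII-PLY, `--delimiter`/`--decimal-separator`
for European CSV dialects, and `--spec` for full control via the XML-like
object-specification text (`u3dkit genspec` emits a skeleton).

From Python (`examples/` has one narrative script per capability):

```python
from u3dkit import *
scene = Scene()
scene.add_resource("loop", make_fixture("helix_line"))
add_model(scene, apply_defaults(ObjectSpec(
    object_type="lineset", geometry_id="loop", name="Loop",
    diffuse=(0.8, 0.1, 0.1), opacity=0.5)), "loop")
save_u3d(scene, "loop.u3d")
decoded = decode_scene(open("loop.u3d", "rb").read())   # the oracle
```

Embedding the result into a PDF is one `\includemedia` call with LaTeX +
media9; the manual viewer check is documented in `docs/pdf_embedding.md`.

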