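# Methods: what u3dkit writes and why

This note records the model behind the package — the emitted U3D subset,
the codec, the numeric choices and the limits of what the tests show.

## Scene model

A scene is a rooted tree of named nodes (groups and models) plus a table
of geometry resources and ordered file-level metadata pairs. Models
reference resources by id; any number of models may reference one
resource, and the resource is serialized exactly once — this is the
mechanism that keeps "same shape, different color/transparency" files
small, and the size advantage is asserted by test and measured by the
acceptance script. Sibling name clashes are auto-suffixed (`_2`, `_3`, …)
with a warning rather than aborting an export over a cosmetic clash; node
names must still be unique across the whole tree at encode time because
U3D links children to parents *by name*.

Coordinates pass through unchanged (no unit handling, right-handed axes
assumed, matching U3D viewers); transforms default to identity and are
written as-is. Geometry arrays are stored as 32-bit floats on
construction because that is the container's precision — "bit-exact mesh
round trip" means exactness at float32.

Per-vertex normals, when absent, are computed as the normalized
area-weighted average of incident face normals (accumulating raw edge
cross products, whose magnitude is twice the face area, *is* the area
weighting); faces wind counter-clockwise under the right-hand rule.
Vertices incident only to zero-area faces get the (0, 0, 1) fallback with
a warning. Degenerate faces (repeated vertex) and zero-length edges are
dropped with a warning before export.

Material defaults when a spec omits them: diffuse (0.65, 0.65, 0.65),
specular (0.3, 0.3, 0.3), ambient = 0.1 × diffuse, emissive black,
reflectivity 0, opacity 1 — conventional neutral-gray publication
defaults, configurable in `u3dkit.specs.SPEC_DEFAULTS` and
`default_material`.

## Specification language

Exports are described by `<U3DObject>` records with child tags
ObjectType, ObjectName, GroupPath, GeometryID, Color, SpecularColor,
Opacity and MetaData (Key/Value children). Tags are case-insensitive,
whitespace is free, unknown tags are rejected with the record index
(never silently ignored), and omitted tags take the defaults above. The
tag vocabulary is this package's own versioned design, chosen to be
round-trip-testable: `parse(generate(s)) == [s]` is property-tested, and
`generate(..., compact=True)` omits default-valued fields. No
compatibility with any other tool's specification strings is claimed.
Deleting records is plain text editing.

## Tabular import

`read_marker_list` reads one 3D position per surviving row; fields beyond
x, y, z are ignored because real marker files carry labels and
timestamps. The dialect is explicit: single-character value delimiter
(whitespace runs collapse when the delimiter is a space), decimal
separator substituted before numeric parsing (a `.` inside a field is an
error when the separator is `,` — it would silently mean thousands
otherwise), `#` comments. The row filter keeps row `i` (0-based, counted
after comment/blank removal) iff `i ≥ start`, `(i − start) mod stride =
0` and the optional column match holds, truncated at `max_rows`; this is
deliberately a superset of "import only a subset" and is verified against
a brute-force row scan. Error messages carry 1-based physical line
numbers. When a line set arrives without a connection list, the automatic
rule joins each node to the next: n positions → max(n−1, 0) segments.

## The byte format

Every block is `type:u32 | data-size:u32 | metadata-size:u32`, data and
metadata each zero-padded to a 32-bit boundary, sizes counting unpadded
bytes. The file is: header block (type 0x00443355, bytes `U 3 D \0`;
version, profile, declaration size, file size, UTF-8 encoding code 106;
scene metadata rides in the header's metadata section as attribute-tagged
key/value strings) — declaration section — continuation section. The
declared declaration/file sizes are patched after assembly and always
equal the true byte counts; output is deterministic (no timestamps), so
byte-level regression tests are possible.

Nodes and geometry declarations live inside modifier-chain blocks (nodes:
group/model chains, the model chain also carrying a shading modifier that
binds the model to its shader; resources: one chain per geometry
declaration). Shaders, materials and the optional light/view resources
are standalone blocks. Materials are deduplicated by value: models with
identical appearance share one material/shader pair. Opacity < 1 selects
the alpha-blend framebuffer function in the shader; opacity 1 selects the
opaque one.

Emitted block types: file header, modifier chain, group/model/light/view
node, CLOD mesh declaration + base mesh continuation, point/line set
declaration + continuation, shading modifier, lit texture shader,
material resource, light/view resource. The reader supports exactly this
subset, skips unknown block types using their declared sizes, and rejects
progressive meshes (min ≠ max resolution), multi-parent nodes and
per-vertex color channels as out of subset.

## Bit codec

Block payloads are bit streams (LSB-first within little-endian words)
from a 16-bit integer arithmetic coder with carry-free renormalization
and underflow bit-stuffing, driven by the U3D context model:

* **Context8** — fixed uniform over 256 symbols; all uncompressed
  primitives are built from it, with bytes bit-reversed so that a
  byte-aligned uncompressed write emits the plain little-endian bytes
  (a property test asserts this verbatim-bytes behavior; it is what makes
  uncompressed-only blocks byte-level standard-shaped).
* **Static contexts** (id = 0x400 + range) — uniform over `range`
  symbols, stateless; used for face corner indices and line endpoint
  references. Ranges beyond 0x3FFF fall back to uncompressed writes,
  computed identically on both sides (relevant only for meshes with more
  than 16383 vertices, whose indices then travel uncompressed).
* **Dynamic contexts** — adaptive histograms with escape symbol 0;
  unseen values escape to an uncompressed write and are then added on
  both sides. Totals halve at 0x1FFF (the escape count is kept ≥ 1);
  symbols ≥ 0xFFFF never enter a histogram. Used for coordinate
  difference signs/magnitudes and per-element counts. Dynamic context
  *numbers* are internal labels — they select histograms but never reach
  the byte stream.

At end of payload the coder, if its interval state is pending, emits one
disambiguation bit plus stuffed underflow bits so that the zero-padded
stream decodes completely; the decoder treats bits past the end as zero.
Conformance contract: the package guarantees decode-equivalence through
its own reader (the stated oracle); byte-equality with other U3D
implementations is not claimed.

## Geometry payloads

* **Meshes** — declaration carries counts, attribute flags (bit 0 =
  normals excluded), one shading description (no per-vertex colors or
  texture layers), minimum = maximum resolution = vertex count, quality
  factors, inverse quantization steps and resource parameters (crease
  0.9, update 0.5, tolerance 0.985 — informational for a full-resolution
  export). The base mesh continuation writes positions (and per-vertex
  normals unless excluded) as raw f32 triples, then per face a shading id
  (dynamic context) and per corner position/normal indices (static
  contexts sized by the counts). No progressive updates are emitted.
* **Point sets** — one point per position. Per new position: a split
  index (static context; the previous position acts as predictor), sign
  bits and per-axis magnitudes of the quantized difference (dynamic
  contexts), a normal count (always 0 in this subset), a new-point count
  (1) and a shading id.
* **Line sets** — positions as for point sets; each edge is attached to
  its larger-index endpoint and written as (other-endpoint index in a
  static context, shading id) when that position is emitted. Decoded
  edge lists are therefore position-major with (min, max) orientation;
  tests compare edge multisets, counts and chain topology, which is the
  preserved contract. Self-loop edges cannot be represented and are
  dropped (with warning) during validation.

Quantization uses `q = rint(x · f)` per axis (ties to even — irrelevant
to the bound), signed magnitudes below 2³¹ enforced; the decoded value
`q / f` is within `0.5 / f` of the stored float32 coordinate, plus at
most half an ulp from re-entering the float32 container. Default `f` =
1000 ≈ three decimal digits; configurable per export
(`QuantizationParams`). Zero is a fixed point: a point at the origin
decodes exactly.

## Lights and views

Both are optional and **off** by default — PDF viewers supply usable
defaults, and fewer blocks mean smaller files. When enabled: one ambient
light resource + node; one perspective view whose camera sits at the
scene bounding-box center + (0, 0, d), d = max(1, 2.5 × bounding radius),
fov 35°, near = d/100, far = 10·d. The fixed far/d ratio lets the reader
recover the framed target as `position − (0, 0, far/10)`, which the
framing test checks against the true box center.

## Synthetic data

`make_fixture` produces the four deterministic test shapes: an
`nx×ny×nz` lattice (default 3×3×3, optional seeded jitter), a 100-sample
helix polyline (3 turns, radius 1, height 2 — a stand-in for trajectory
data), a unit cube (8 vertices/12 faces, closed, outward CCW winding) and
a subdivided-icosahedron sphere (20·4^s faces; s = 2 → 320 faces).
`random_scene(seed)` assembles 1–3 objects over these with nested groups,
shared resources, random colors/opacities and optional metadata. These
fixtures exercise every code path (all geometry kinds, sharing,
transparency, hierarchy) but are small and regular; passing tests bound
coding/decoding correctness and the stated tolerances, not viewer
behavior on pathological real-world meshes (self-intersections,
inconsistent winding, huge coordinate ranges) — the manual viewer check
in `pdf_embedding.md` and the quantization-overflow guard cover that
boundary.

## Known limitations

No textures (hence no simulated volume rendering), animation, glyphs,
per-vertex colors/texture coordinates, bones or progressive CLOD levels;
PRC output and PDF document authoring are out of scope (standard PDF
tools handle the embedding). Binary PLY and STL are not read. The reader
is an oracle for this encoder's subset, not a general U3D importer.
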