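# Manual check: embedding a produced U3D file into a 3D PDF

The automated test suite verifies U3D files structurally (framing,
alignment, codec inversion, geometry round trip through the package's own
reader). The final oracle — *does a stock PDF viewer display the scene?* —
cannot run in CI because it needs a desktop viewer. This page documents the
manual procedure; run it whenever the emitted block layouts change.

## 1. Produce a test file

```sh
python examples/mixed_scene.py          # writes scratch/mixed.u3d
# or:
u3dkit convert --points points.csv --lines track.csv --mesh organ.obj \
       -o model.u3d
```

A good test scene contains all three geometry kinds, one object with
opacity < 1, and a two-level group hierarchy.

## 2. Embed with LaTeX + media9

`media9` is the standard free authoring route for PDF 3D annotations.
Compile the following with `pdflatex` (TeX Live; `lualatex` also works):

```latex
\documentclass{article}
\usepackage{media9}
\begin{document}
\includemedia[
  width=0.9\linewidth, height=0.9\linewidth,
  activate=pageopen,
  3Dtoolbar, 3Dmenu,
  3Dviews=,
]{}{model.u3d}
\end{document}
```

Alternatively, the iText (Java) library can attach a U3D stream to a PDF 3D
annotation programmatically; any authoring tool that accepts ECMA-363
streams is suitable.

## 3. Inspect in Adobe Reader

Open the PDF in Adobe Acrobat Reader (the reference implementation for PDF
3D annotations; other viewers often skip 3D content) and click the
annotation to activate it. Check that:

- every exported object is present and selectable in the model tree panel,
  with the group hierarchy and names from the object specifications;
- point clouds render as dots, line sets as connected polylines (a
  converted trajectory must be one unbroken chain), meshes as shaded
  surfaces;
- colors match the specs, and objects with opacity < 1 are transparent;
- orbit/zoom/pan behave normally and nothing vanishes at odd angles
  (a winding/normal problem would show up here).

`u3dkit inspect model.u3d` prints the same object/element counts the model
tree should show.

## Caveat

This package's reader guarantees decode-equivalence for the emitted block
subset; it is the structural oracle, not a rendering oracle. Viewer
behavior for files produced after layout changes must be confirmed with
this procedure.
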