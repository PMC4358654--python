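"""The XML-like object-specification language.

An export is described by a sequence of ``<U3DObject>`` records, each naming
one visible object: what kind of geometry it is, which imported geometry it
uses, where it sits in the object tree and how it is colored. Example::

    <U3DObject>
      <ObjectType>Mesh</ObjectType>
      <ObjectName>LeftVentricle</ObjectName>
      <GroupPath>Heart/Chambers</GroupPath>
      <GeometryID>0</GeometryID>
      <Color>0.8 0.1 0.1</Color>
      <Opacity>0.5</Opacity>
      <MetaData><Key>source</Key><Value>segmentation</Value></MetaData>
    </U3DObject>

Tags are case-insensitive and whitespace-tolerant; omitted tags fall back to
the defaults in :data:`SPEC_DEFAULTS`. Unknown tags are rejected (never
silently ignored). The concrete tag vocabulary is this package's own,
versioned design — it is round-trip-testable and diff-friendly; no syntax
compatibility with other exporters is claimed. Deleting records is plain
text editing; there is no API beyond list manipulation.
"""

from __future__ import annotations

import io
import re
import xml.etree.ElementTree as ET
from xml.sax.saxutils import escape as _xml_escape
from dataclasses import dataclass, field, replace

from .errors import U3DSpecError

__all__ = ["ObjectSpec", "SPEC_DEFAULTS", "OBJECT_TYPES",
           "parse_spec", "generate_spec", "apply_defaults"]

OBJECT_TYPES = ("pointset", "lineset", "mesh")

#: Configurable default table applied to omitted fields.
SPEC_DEFAULTS = {
    "group_path": "/",
    "diffuse": (0.65, 0.65, 0.65),
    "specular": (0.3, 0.3, 0.3),
    "opacity": 1.0,
}

_KNOWN_TAGS = {"objecttype", "objectname", "grouppath", "geometryid",
               "color", "specularcolor", "opacity", "metadata"}
_CANONICAL_TYPE = {"pointset": "PointSet", "lineset": "LineSet", "mesh": "Mesh"}


@dataclass
class ObjectSpec:
    """Declarative description of one exported object."""

    object_type: str                       # "pointset" | "lineset" | "mesh"
    geometry_id: str
    name: str | None = None
    group_path: str = SPEC_DEFAULTS["group_path"]
    diffuse: tuple[float, float, float] = SPEC_DEFAULTS["diffuse"]
    opacity: float = SPEC_DEFAULTS["opacity"]
    specular: tuple[float, float, float] = SPEC_DEFAULTS["specular"]
    metadata: list[tuple[str, str]] = field(default_factory=list)

    def validate(self) -> None:
        if self.object_type not in OBJECT_TYPES:
            raise U3DSpecError(
                f"object_type must be one of {OBJECT_TYPES}, "
                f"got {self.object_type!r}")
        if not self.geometry_id:
            raise U3DSpecError("geometry_id must be non-empty")
        for label, rgb in (("Color", self.diffuse),
                           ("SpecularColor", self.specular)):
            if len(rgb) != 3 or any(not 0.0 <= c <= 1.0 for c in rgb):
                raise U3DSpecError(f"{label} channels must lie in [0, 1]: {rgb}")
        if not 0.0 <= self.opacity <= 1.0:
            raise U3DSpecError(f"Opacity must lie in [0, 1]: {self.opacity}")


def apply_defaults(spec: ObjectSpec, ordinal: int = 1) -> ObjectSpec:
    """Fill every optional field from the default table.

    ``object_type`` and ``geometry_id`` must already be present. An omitted
    name becomes ``"<type>_<ordinal>"``.
    """
    if spec.object_type not in OBJECT_TYPES:
        raise U3DSpecError(f"unknown object type {spec.object_type!r}")
    if not spec.geometry_id:
        raise U3DSpecError("geometry_id is required")
    out = spec
    if not out.name:
        out = replace(out, name=f"{out.object_type}_{ordinal}")
    if not out.group_path:
        out = replace(out, group_path=SPEC_DEFAULTS["group_path"])
    out.validate()
    return out


def _parse_rgb(text: str, tag: str, record: int) -> tuple[float, float, float]:
    parts = [p for p in re.split(r"[,\s]+", text.strip()) if p]
    if len(parts) != 3:
        raise U3DSpecError(
            f"record {record}: {tag} needs 3 channels, got {text!r}")
    try:
        rgb = tuple(float(p) for p in parts)
    except ValueError:
        raise U3DSpecError(
            f"record {record}: unparseable {tag} value {text!r}") from None
    if any(not 0.0 <= c <= 1.0 for c in rgb):
        raise U3DSpecError(
            f"record {record}: {tag} channels out of [0, 1]: {text!r}")
    return rgb


def _parse_metadata(elem: ET.Element, record: int) -> tuple[str, str]:
    key = value = None
    for child in elem:
        tag = child.tag.lower()
        if tag == "key":
            key = child.text or ""
        elif tag == "value":
            value = child.text or ""
        else:
            raise U3DSpecError(
                f"record {record}: unknown tag <{child.tag}> inside <MetaData>")
    if key is None or value is None:
        raise U3DSpecError(
            f"record {record}: <MetaData> needs <Key> and <Value> children")
    return key, value


def parse_spec(text: str) -> list[ObjectSpec]:
    """Parse specification text into one ObjectSpec per record, in order."""
    try:
        root = ET.fromstring(f"<SpecList>{text}</SpecList>")
    except ET.ParseError as e:
        raise U3DSpecError(f"specification text is not well formed: {e}") from e
    specs: list[ObjectSpec] = []
    counters = dict.fromkeys(OBJECT_TYPES, 0)
    for idx, rec in enumerate(root):
        if rec.tag.lower() != "u3dobject":
            raise U3DSpecError(
                f"record {idx}: expected <U3DObject>, found <{rec.tag}>")
        fields: dict = {"metadata": []}
        for child in rec:
            tag = child.tag.lower()
            if tag not in _KNOWN_TAGS:
                raise U3DSpecError(
                    f"record {idx}: unknown tag <{child.tag}>")
            text_val = (child.text or "").strip()
            if tag == "objecttype":
                t = text_val.lower()
                if t not in OBJECT_TYPES:
                    raise U3DSpecError(
                        f"record {idx}: unknown ObjectType {text_val!r}")
                fields["object_type"] = t
            elif tag == "objectname":
                fields["name"] = text_val
            elif tag == "grouppath":
                fields["group_path"] = text_val or "/"
            elif tag == "geometryid":
                fields["geometry_id"] = text_val
            elif tag == "color":
                fields["diffuse"] = _parse_rgb(text_val, "Color", idx)
            elif tag == "specularcolor":
                fields["specular"] = _parse_rgb(text_val, "SpecularColor", idx)
            elif tag == "opacity":
                try:
                    fields["opacity"] = float(text_val)
                except ValueError:
                    raise U3DSpecError(
                        f"record {idx}: unparseable Opacity "
                        f"{text_val!r}") from None
            elif tag == "metadata":
                fields["metadata"].append(_parse_metadata(child, idx))
        if "object_type" not in fields:
            raise U3DSpecError(f"record {idx}: missing ObjectType")
        if "geometry_id" not in fields or not fields["geometry_id"]:
            raise U3DSpecError(f"record {idx}: missing GeometryID")
        spec = ObjectSpec(**fields)
        counters[spec.object_type] += 1
        try:
            spec = apply_defaults(spec, ordinal=counters[spec.object_type])
        except U3DSpecError as e:
            raise U3DSpecError(f"record {idx}: {e}") from None
        specs.append(spec)
    return specs


def _fmt_rgb(rgb) -> str:
    return " ".join(repr(float(c)) for c in rgb)


def generate_spec(spec: ObjectSpec, compact: bool = False) -> str:
    """Emit one ``<U3DObject>`` record that :func:`parse_spec` inverts exactly.

    With ``compact`` set, fields equal to their defaults are omitted.
    """
    spec.validate()
    if not spec.name:
        raise U3DSpecError("generate_spec requires a named spec "
                           "(run apply_defaults first)")
    out = io.StringIO()
    out.write("<U3DObject>\n")
    out.write(f"  <ObjectType>{_CANONICAL_TYPE[spec.object_type]}"
              "</ObjectType>\n")
    out.write(f"  <ObjectName>{_xml_escape(spec.name)}</ObjectName>\n")
    out.write(f"  <GeometryID>{_xml_escape(spec.geometry_id)}</GeometryID>\n")
    if not (compact and spec.group_path == SPEC_DEFAULTS["group_path"]):
        out.write(f"  <GroupPath>{_xml_escape(spec.group_path)}</GroupPath>\n")
    if not (compact and tuple(spec.diffuse) == SPEC_DEFAULTS["diffuse"]):
        out.write(f"  <Color>{_fmt_rgb(spec.diffuse)}</Color>\n")
    if not (compact and tuple(spec.specular) == SPEC_DEFAULTS["specular"]):
        out.write(f"  <SpecularColor>{_fmt_rgb(spec.specular)}"
                  "</SpecularColor>\n")
    if not (compact and spec.opacity == SPEC_DEFAULTS["opacity"]):
        out.write(f"  <Opacity>{spec.opacity!r}</Opacity>\n")
    for key, value in spec.metadata:
        out.write(f"  <MetaData><Key>{_xml_escape(key)}</Key>"
                  f"<Value>{_xml_escape(value)}</Value></MetaData>\n")
    out.write("</U3DObject>\n")
    return out.getvalue()
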