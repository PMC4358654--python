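"""Object-specification language: parsing, generation, defaults, round trip."""

import pytest
from hypothesis import given, strategies as st

from u3dkit import (ObjectSpec, U3DSpecError, apply_defaults, generate_spec,
                    parse_spec)
from u3dkit.specs import OBJECT_TYPES, SPEC_DEFAULTS

MINIMAL = """
<U3DObject>
  <ObjectType>PointSet</ObjectType>
  <ObjectName>P</ObjectName>
  <GeometryID>0</GeometryID>
</U3DObject>
"""


class TestParse:
    def test_defaults_applied(self):
        (spec,) = parse_spec(MINIMAL)
        assert spec.name == "P"
        assert spec.object_type == "pointset"
        assert spec.diffuse == SPEC_DEFAULTS["diffuse"]
        assert spec.specular == SPEC_DEFAULTS["specular"]
        assert spec.opacity == 1.0
        assert spec.group_path == "/"

    def test_tags_case_insensitive(self):
        text = MINIMAL.replace("ObjectType", "OBJECTTYPE").replace(
            "ObjectName", "objectname")
        (spec,) = parse_spec(text)
        assert spec.name == "P"

    def test_record_order_preserved(self):
        two = MINIMAL + MINIMAL.replace(">P<", ">Q<")
        specs = parse_spec(two)
        assert [s.name for s in specs] == ["P", "Q"]

    def test_unknown_tag_names_tag_and_record(self):
        bad = MINIMAL.replace("</U3DObject>",
                              "<Texture>x</Texture></U3DObject>")
        with pytest.raises(U3DSpecError, match=r"record 0.*Texture"):
            parse_spec(bad)

    def test_opacity_out_of_range(self):
        bad = MINIMAL.replace("</U3DObject>",
                              "<Opacity>1.5</Opacity></U3DObject>")
        with pytest.raises(U3DSpecError, match="Opacity"):
            parse_spec(bad)

    def test_unparseable_color(self):
        bad = MINIMAL.replace("</U3DObject>",
                              "<Color>red</Color></U3DObject>")
        with pytest.raises(U3DSpecError, match="Color"):
            parse_spec(bad)

    @pytest.mark.parametrize("missing", ["ObjectType", "GeometryID"])
    def test_required_tags(self, missing):
        import re
        bad = re.sub(rf"\s*<{missing}>.*</{missing}>", "", MINIMAL)
        with pytest.raises(U3DSpecError, match=missing):
            parse_spec(bad)

    def test_metadata_pair(self):
        text = MINIMAL.replace(
            "</U3DObject>",
            "<MetaData><Key>author</Key><Value>X</Value></MetaData>"
            "</U3DObject>")
        (spec,) = parse_spec(text)
        assert spec.metadata == [("author", "X")]

    def test_omitted_name_autonamed_per_type(self):
        text = 2 * MINIMAL.replace("  <ObjectName>P</ObjectName>\n", "")
        specs = parse_spec(text)
        assert [s.name for s in specs] == ["pointset_1", "pointset_2"]


class TestGenerate:
    def test_minimal_record_is_single_record(self):
        spec = apply_defaults(ObjectSpec("pointset", "0", name="P"))
        text = generate_spec(spec)
        assert text.count("<U3DObject>") == 1
        assert parse_spec(text) == [spec]

    def test_metadata_emitted(self):
        spec = apply_defaults(ObjectSpec("mesh", "0", name="M",
                                         metadata=[("author", "X")]))
        text = generate_spec(spec)
        assert "author" in text and "X" in text
        assert parse_spec(text)[0].metadata == [("author", "X")]

    def test_compact_omits_defaults(self):
        spec = apply_defaults(ObjectSpec("mesh", "0", name="M"))
        assert "<Color>" not in generate_spec(spec, compact=True)
        assert parse_spec(generate_spec(spec, compact=True)) == [spec]

    def test_invalid_spec_rejected(self):
        with pytest.raises(U3DSpecError):
            generate_spec(ObjectSpec("mesh", "0", name="M", opacity=2.0))


class TestApplyDefaults:
    def test_group_path_default(self):
        spec = apply_defaults(ObjectSpec("mesh", "0", name="M",
                                         group_path=""))
        assert spec.group_path == "/"

    def test_specular_default(self):
        spec = apply_defaults(ObjectSpec("mesh", "0", name="M"))
        assert spec.specular == (0.3, 0.3, 0.3)

    def test_autoname_uses_type_and_ordinal(self):
        spec = apply_defaults(ObjectSpec("lineset", "7"), ordinal=4)
        assert spec.name == "lineset_4"

    def test_requires_type_and_geometry(self):
        with pytest.raises(U3DSpecError):
            apply_defaults(ObjectSpec("volume", "0"))
        with pytest.raises(U3DSpecError):
            apply_defaults(ObjectSpec("mesh", ""))


_name = st.text(
    alphabet=st.characters(codec="utf-8",
                           blacklist_categories=("Cc", "Cs", "Zs", "Zl", "Zp")),
    min_size=1, max_size=12)
_channel = st.integers(0, 100).map(lambda v: v / 100.0)
_rgb = st.tuples(_channel, _channel, _channel)


@st.composite
def object_specs(draw):
    return apply_defaults(ObjectSpec(
        object_type=draw(st.sampled_from(OBJECT_TYPES)),
        geometry_id=draw(_name),
        name=draw(_name),
        group_path=draw(st.one_of(
            st.just("/"),
            st.lists(_name, min_size=1, max_size=3).map("/".join))),
        diffuse=draw(_rgb),
        specular=draw(_rgb),
        opacity=draw(_channel),
        metadata=draw(st.lists(st.tuples(_name, _name), max_size=2)),
    ))


@given(spec=object_specs(), compact=st.booleans())
def test_parse_inverts_generate(spec, compact):
    assert parse_spec(generate_spec(spec, compact=compact)) == [spec]
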