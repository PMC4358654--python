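"""Write and parse the XML-like object-specification text.

The specification text is the declarative interface between "I have
geometry" and "this is what the exported objects look like": it can be
generated, versioned, diffed and edited by hand.
"""

from u3dkit import ObjectSpec, apply_defaults, generate_spec, parse_spec

spec = apply_defaults(ObjectSpec(
    object_type="mesh", geometry_id="0", name="LeftVentricle",
    group_path="Heart/Chambers", diffuse=(0.8, 0.1, 0.1), opacity=0.5,
    metadata=[("source", "segmentation run 12")]))

text = generate_spec(spec)
print(text)
(back,) = parse_spec(text)
print("round trip exact:", back == spec)
# parse(generate(s)) == s field-for-field: the text is a faithful,
# re-editable serialization of the object description.
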