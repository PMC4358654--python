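"""Numeric constants of the emitted U3D (ECMA-363) block subset.

Everything the encoder and reader share lives here: block-type codes, the
bit-codec's context-model constants, and the flag values used in the block
layouts. Block-type codes follow the ECMA-363 Universal 3D block-type
table; the dynamic compression-context numbers at the bottom are this
writer's internal allocation — context numbers select histograms but never
appear in the byte stream, so any consistent assignment decodes
identically.
"""

from __future__ import annotations

# --- block types -----------------------------------------------------------
# File structure blocks
BT_FILE_HEADER = 0x00443355        # little-endian bytes 'U' '3' 'D' \0
BT_MODIFIER_CHAIN = 0xFFFFFF14
BT_PRIORITY_UPDATE = 0xFFFFFF15
# Node blocks
BT_GROUP_NODE = 0xFFFFFF21
BT_MODEL_NODE = 0xFFFFFF22
BT_LIGHT_NODE = 0xFFFFFF23
BT_VIEW_NODE = 0xFFFFFF24
# Geometry generator blocks (declaration + continuation)
BT_CLOD_MESH_DECL = 0xFFFFFF31
BT_BASE_MESH_CONT = 0xFFFFFF3B
BT_POINT_SET_DECL = 0xFFFFFF36
BT_POINT_SET_CONT = 0xFFFFFF3E
BT_LINE_SET_DECL = 0xFFFFFF37
BT_LINE_SET_CONT = 0xFFFFFF3F
# Modifier blocks
BT_SHADING_MODIFIER = 0xFFFFFF45
# Resource blocks
BT_LIGHT_RESOURCE = 0xFFFFFF51
BT_VIEW_RESOURCE = 0xFFFFFF52
BT_LIT_SHADER = 0xFFFFFF53
BT_MATERIAL_RESOURCE = 0xFFFFFF54

BLOCK_KIND_NAMES = {
    BT_FILE_HEADER: "file header",
    BT_MODIFIER_CHAIN: "modifier chain",
    BT_PRIORITY_UPDATE: "priority update",
    BT_GROUP_NODE: "group node",
    BT_MODEL_NODE: "model node",
    BT_LIGHT_NODE: "light node",
    BT_VIEW_NODE: "view node",
    BT_CLOD_MESH_DECL: "mesh declaration",
    BT_BASE_MESH_CONT: "mesh continuation",
    BT_POINT_SET_DECL: "point set declaration",
    BT_POINT_SET_CONT: "point set continuation",
    BT_LINE_SET_DECL: "line set declaration",
    BT_LINE_SET_CONT: "line set continuation",
    BT_SHADING_MODIFIER: "shading modifier",
    BT_LIGHT_RESOURCE: "light resource",
    BT_VIEW_RESOURCE: "view resource",
    BT_LIT_SHADER: "lit texture shader",
    BT_MATERIAL_RESOURCE: "material resource",
}

# --- file header -----------------------------------------------------------
FILE_VERSION = 0                   # base version, no extensions
PROFILE_BASE = 0                   # base profile (no optional features)
CHAR_ENCODING_UTF8 = 106           # IANA MIBenum for UTF-8

# --- modifier chains -------------------------------------------------------
CHAIN_TYPE_NODE = 0
CHAIN_TYPE_MODEL_RESOURCE = 1

# --- node / shading flags --------------------------------------------------
MODEL_VISIBILITY_BOTH = 3          # front and back faces visible
SHADING_ATTR_MESH = 0x00000001
SHADING_ATTR_LINE = 0x00000002
SHADING_ATTR_POINT = 0x00000004

# --- mesh declaration attributes ------------------------------------------
MESH_ATTR_DEFAULT = 0x00000000
MESH_ATTR_EXCLUDE_NORMALS = 0x00000001

# --- material / shader -----------------------------------------------------
MATERIAL_ATTR_ALL = 0x0000003F     # ambient|diffuse|specular|emissive|refl|opacity
SHADER_ATTR_LIGHTING = 0x00000001
ALPHA_TEST_ALWAYS = 0x00000617
BLEND_OPAQUE = 0x00000600          # framebuffer blend: replace
BLEND_ALPHA = 0x00000606           # framebuffer blend: alpha blending

# --- lights ----------------------------------------------------------------
LIGHT_TYPE_AMBIENT = 0
LIGHT_ATTR_ENABLED = 0x00000001

# --- bit-codec context model ----------------------------------------------
CTX_UNCOMPRESSED_U8 = 0            # "Context8": uniform over 256 symbols
STATIC_FULL = 0x00000400           # first static context id
MAX_STATIC_RANGE = 0x00003FFF      # largest value range a static context holds
MAX_CONTEXT = STATIC_FULL + MAX_STATIC_RANGE
ELEPHANT = 0x00001FFF              # histogram total triggering a rescale
MAX_HISTOGRAM_SYMBOL = 0x0000FFFF  # larger symbols always escape

# Dynamic contexts used by the geometry continuation layouts (internal
# numbering; see module docstring).
CTX_SHADING_ID = 1
CTX_POS_DIFF_SIGN = 2
CTX_POS_DIFF_X = 3
CTX_POS_DIFF_Y = 4
CTX_POS_DIFF_Z = 5
CTX_NORMAL_COUNT = 6
CTX_POINT_COUNT = 7
CTX_LINE_COUNT = 8


def static_context(value_range: int) -> int:
    """Context id for a value uniformly coded in ``[0, value_range)``.

    Ranges beyond the static-context capacity return an id past
    ``MAX_CONTEXT``; the codec then falls back to uncompressed writes (both
    sides compute the context from the same counts, so they agree).
    """
    if value_range < 1:
        raise ValueError("static context needs a positive value range")
    return STATIC_FULL + value_range
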