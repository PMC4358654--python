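"""Typed, 32-bit-aligned binary blocks — the U3D on-disk unit.

A serialized block is::

    block type (u32) | data size (u32) | metadata size (u32)
    data  ... zero-padded to a 32-bit boundary
    metadata ... zero-padded to a 32-bit boundary

Declared sizes count the unpadded bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import BLOCK_KIND_NAMES
from .errors import U3DParseError

__all__ = ["U3DBlock", "BlockSummary", "parse_blocks", "serialize_blocks",
           "padded_size"]

_HEADER_BYTES = 12


def _pad4(data: bytes) -> bytes:
    return data + b"\0" * (-len(data) % 4)


def padded_size(block: "U3DBlock") -> int:
    """Full serialized extent of a block including header and padding."""
    return (_HEADER_BYTES + len(block.data) + (-len(block.data) % 4)
            + len(block.metadata) + (-len(block.metadata) % 4))


@dataclass
class U3DBlock:
    block_type: int
    data: bytes
    metadata: bytes = b""

    def serialize(self) -> bytes:
        head = (self.block_type.to_bytes(4, "little")
                + len(self.data).to_bytes(4, "little")
                + len(self.metadata).to_bytes(4, "little"))
        return head + _pad4(self.data) + _pad4(self.metadata)


def serialize_blocks(blocks: list[U3DBlock]) -> bytes:
    return b"".join(b.serialize() for b in blocks)


@dataclass
class BlockSummary:
    """Structural description of one block as found in a byte stream."""

    offset: int
    block_type: int
    data_size: int
    metadata_size: int
    kind: str = field(default="unknown")
    block: U3DBlock | None = None

    @property
    def padded_extent(self) -> int:
        return (_HEADER_BYTES + self.data_size + (-self.data_size % 4)
                + self.metadata_size + (-self.metadata_size % 4))


def parse_blocks(data: bytes, *, base_offset: int = 0) -> list[BlockSummary]:
    """Exact partition of a byte stream into aligned blocks.

    Unknown block types are reported with kind ``"unknown"``, not rejected.
    Truncated or size-overrunning blocks raise with the failing offset.
    """
    if len(data) < _HEADER_BYTES:
        raise U3DParseError(
            f"stream of {len(data)} bytes is shorter than a block header",
            offset=base_offset)
    out: list[BlockSummary] = []
    pos = 0
    while pos < len(data):
        if pos % 4:
            raise U3DParseError("misaligned block start",
                                offset=base_offset + pos)
        if pos + _HEADER_BYTES > len(data):
            raise U3DParseError(
                "truncated block header", offset=base_offset + pos)
        btype = int.from_bytes(data[pos:pos + 4], "little")
        dsize = int.from_bytes(data[pos + 4:pos + 8], "little")
        msize = int.from_bytes(data[pos + 8:pos + 12], "little")
        summary = BlockSummary(
            offset=base_offset + pos, block_type=btype,
            data_size=dsize, metadata_size=msize,
            kind=BLOCK_KIND_NAMES.get(btype, "unknown"))
        end = pos + summary.padded_extent
        if end > len(data):
            raise U3DParseError(
                f"block data overruns stream (needs {end - len(data)} more "
                "bytes)", offset=base_offset + pos)
        dstart = pos + _HEADER_BYTES
        mstart = dstart + dsize + (-dsize % 4)
        summary.block = U3DBlock(
            block_type=btype,
            data=data[dstart:dstart + dsize],
            metadata=data[mstart:mstart + msize])
        out.append(summary)
        pos = end
    return out
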