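"""Bit codec: primitive channels, alignment, inversion under fuzzing."""

import random
import struct

import pytest
from hypothesis import given, strategies as st

from u3dkit.bitio import BitReader, BitWriter
from u3dkit.constants import MAX_STATIC_RANGE, STATIC_FULL
from u3dkit.errors import U3DEncodeError


class TestUncompressedChannels:
    def test_u32_little_endian(self):
        w = BitWriter()
        w.write_u32(1)
        assert w.finish() == b"\x01\x00\x00\x00"

    def test_aligned_stream_is_plain_bytes(self):
        # Byte-aligned uncompressed channels must serialize verbatim: this
        # is what makes uncompressed-only blocks byte-for-byte standard.
        w = BitWriter()
        w.write_u32(0xDEADBEEF)
        w.write_u16(0x1234)
        w.write_u8(0x56)
        w.write_u64(0x0102030405060708)
        w.write_f32(1.5)
        w.write_string("AB")
        expected = (b"\xef\xbe\xad\xde" + b"\x34\x12" + b"\x56"
                    + bytes([8, 7, 6, 5, 4, 3, 2, 1])
                    + struct.pack("<f", 1.5) + b"\x02\x00AB")
        assert w.finish() == expected

    def test_string_round_trip_utf8(self):
        w = BitWriter()
        w.write_string("héllo – 世界")
        r = BitReader(w.finish())
        assert r.read_string() == "héllo – 世界"

    def test_out_of_range_rejected(self):
        w = BitWriter()
        with pytest.raises(U3DEncodeError):
            w.write_u16(1 << 16)
        with pytest.raises(U3DEncodeError):
            w.write_u8(-1)

    def test_string_length_capacity(self):
        w = BitWriter()
        with pytest.raises(U3DEncodeError):
            w.write_string("x" * 70000)


class TestCompressedChannels:
    def test_static_context_round_trip(self):
        w = BitWriter()
        values = [0, 4, 9, 9, 3]
        for v in values:
            w.write_compressed_u32(STATIC_FULL + 10, v)
        r = BitReader(w.finish())
        assert [r.read_compressed_u32(STATIC_FULL + 10)
                for _ in values] == values

    def test_static_range_enforced(self):
        w = BitWriter()
        with pytest.raises(U3DEncodeError):
            w.write_compressed_u32(STATIC_FULL + 10, 10)

    def test_dynamic_escape_then_hit(self):
        # first occurrence escapes to the raw channel, second is coded from
        # the updated histogram; both decode identically
        w = BitWriter()
        for v in [7, 7, 7, 123456, 123456]:
            w.write_compressed_u32(3, v)
        r = BitReader(w.finish())
        assert [r.read_compressed_u32(3) for _ in range(5)] == \
            [7, 7, 7, 123456, 123456]

    def test_oversized_context_falls_back_uncompressed(self):
        ctx = STATIC_FULL + MAX_STATIC_RANGE + 50   # beyond static capacity
        w = BitWriter()
        w.write_compressed_u32(ctx, 99999)
        data = w.finish()
        assert data == (99999).to_bytes(4, "little")
        assert BitReader(data).read_compressed_u32(ctx) == 99999

    def test_repetition_compresses(self):
        w = BitWriter()
        for _ in range(500):
            w.write_compressed_u32(4, 2)
        compressed = len(w.finish())
        assert compressed < 500  # far below 4 bytes/value once adapted


def test_inversion_fuzz_10k():
    """decode(encode(seq)) == seq over 10^4 random (context, value) ops."""
    rnd = random.Random(20240)
    ops = []
    for _ in range(10_000):
        choice = rnd.randrange(6)
        if choice == 0:
            ops.append(("u8", rnd.randrange(256), None))
        elif choice == 1:
            ops.append(("u32", rnd.randrange(1 << 32), None))
        elif choice == 2:
            ops.append(("f32", struct.unpack(
                "<f", struct.pack("<f", rnd.uniform(-1e6, 1e6)))[0], None))
        elif choice == 3:   # dynamic, small alphabet: exercises adaptation
            ops.append(("c32", rnd.randrange(8), rnd.randrange(1, 10)))
        elif choice == 4:   # dynamic, wide values: exercises escapes
            ops.append(("c32", rnd.randrange(1 << 20), rnd.randrange(1, 10)))
        else:
            span = rnd.randrange(1, 2000)
            ops.append(("stat", rnd.randrange(span), STATIC_FULL + span))
    w = BitWriter()
    for kind, value, ctx in ops:
        if kind == "u8":
            w.write_u8(value)
        elif kind == "u32":
            w.write_u32(value)
        elif kind == "f32":
            w.write_f32(value)
        else:
            w.write_compressed_u32(ctx, value)
    r = BitReader(w.finish())
    for kind, value, ctx in ops:
        if kind == "u8":
            got = r.read_u8()
        elif kind == "u32":
            got = r.read_u32()
        elif kind == "f32":
            got = r.read_f32()
        else:
            got = r.read_compressed_u32(ctx)
        assert got == value


@given(st.lists(st.tuples(st.integers(1, 12), st.integers(0, 4000)),
                max_size=300))
def test_inversion_property_dynamic(ops):
    """Histogram adaptation, rescaling and escapes never desynchronize."""
    w = BitWriter()
    for ctx, value in ops:
        w.write_compressed_u32(ctx, value)
    r = BitReader(w.finish())
    assert [r.read_compressed_u32(ctx) for ctx, _ in ops] == \
        [value for _, value in ops]


@given(st.binary(max_size=60))
def test_bytes_survive_u8_channel(payload):
    w = BitWriter()
    for b in payload:
        w.write_u8(b)
    assert w.finish() == payload    # aligned u8s are verbatim
    r = BitReader(payload)
    assert bytes(r.read_u8() for _ in payload) == payload


def test_histogram_rescale_keeps_sync():
    # enough repeats of one symbol to cross the rescale threshold (0x1FFF)
    w = BitWriter()
    for i in range(9000):
        w.write_compressed_u32(2, i % 3)
    r = BitReader(w.finish())
    for i in range(9000):
        assert r.read_compressed_u32(2) == i % 3
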