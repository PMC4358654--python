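"""Stateful bit-level codec with uncompressed and context-compressed channels.

U3D block payloads are bit streams produced by an adaptive binary arithmetic
coder (16-bit integer registers, carry-free renormalization with underflow
bit-stuffing) driven by a *context model*:

* ``Context8`` (context 0) — a fixed uniform distribution over 256 symbols.
  Every uncompressed primitive (u8/u16/u32/u64/f32/string) is built from it.
  Coding a uniform-256 symbol from a byte-aligned canonical coder state
  emits exactly the 8 bits of the byte, so blocks that use only
  uncompressed channels serialize to plain little-endian bytes.
* static contexts — a uniform distribution over ``context - STATIC_FULL``
  symbols; deterministic, no state.
* dynamic contexts — adaptive symbol histograms with an escape symbol
  (index 0). A symbol not yet in the histogram codes the escape and is then
  written out-of-line on an uncompressed channel; both sides add it to the
  histogram afterwards, so encoder and decoder stay synchronized. Totals
  are halved when they reach the ``ELEPHANT`` threshold; symbols at or
  above ``MAX_HISTOGRAM_SYMBOL`` always escape.

Bits are packed least-significant-bit first into bytes (equivalently into
little-endian 32-bit words). For every write primitive there is a read
primitive such that ``read(write(x)) == x`` under the same context
sequence; the reader treats bits past the end of the buffer as zero, which
together with the final flush makes the last symbols decodable.
"""

from __future__ import annotations

import struct

from .constants import (CTX_UNCOMPRESSED_U8, ELEPHANT, MAX_CONTEXT,
                        MAX_HISTOGRAM_SYMBOL, STATIC_FULL)
from .errors import U3DEncodeError, U3DParseError

__all__ = ["BitWriter", "BitReader"]

_HALF = 0x8000
_QUARTER = 0x4000

_REV8 = bytes(int(f"{i:08b}"[::-1], 2) for i in range(256))


class _Histogram:
    """Adaptive symbol histogram for one dynamic context.

    Index 0 is the escape symbol (initial count 1). Counts live in a plain
    list mirrored by a Fenwick tree for O(log n) cumulative queries and
    frequency-to-symbol search.
    """

    __slots__ = ("counts", "tree", "cap", "total")

    def __init__(self):
        self.cap = 8
        self.counts = [0] * self.cap
        self.tree = [0] * (self.cap + 1)
        self.total = 0
        self._bump(0)

    def _bump(self, symbol: int) -> None:
        self.counts[symbol] += 1
        self.total += 1
        i = symbol + 1
        while i <= self.cap:
            self.tree[i] += 1
            i += i & (-i)

    def _rebuild(self) -> None:
        self.tree = [0] * (self.cap + 1)
        for s, c in enumerate(self.counts):
            if c:
                i = s + 1
                while i <= self.cap:
                    self.tree[i] += c
                    i += i & (-i)

    def _grow(self, symbol: int) -> None:
        while self.cap <= symbol:
            self.cap *= 2
        self.counts.extend([0] * (self.cap - len(self.counts)))
        self._rebuild()

    def add(self, symbol: int) -> None:
        if symbol >= MAX_HISTOGRAM_SYMBOL:
            return
        if symbol >= self.cap:
            self._grow(symbol)
        if self.total >= ELEPHANT:
            self.counts = [c >> 1 for c in self.counts]
            if self.counts[0] == 0:
                self.counts[0] = 1      # escape stays codable
            self.total = sum(self.counts)
            self._rebuild()
        self._bump(symbol)

    def freq(self, symbol: int) -> int:
        if symbol >= self.cap:
            return 0
        return self.counts[symbol]

    def cum_below(self, symbol: int) -> int:
        """Sum of counts of all symbols < symbol."""
        if symbol > self.cap:
            symbol = self.cap
        total = 0
        i = symbol
        while i > 0:
            total += self.tree[i]
            i -= i & (-i)
        return total

    def find(self, cumfreq: int) -> int:
        """Smallest symbol whose cumulative range contains ``cumfreq``."""
        pos = 0
        remaining = cumfreq
        step = 1
        while step * 2 <= self.cap:
            step *= 2
        while step:
            nxt = pos + step
            if nxt <= self.cap and self.tree[nxt] <= remaining:
                remaining -= self.tree[nxt]
                pos = nxt
            step >>= 1
        return pos


class _ContextManager:
    __slots__ = ("histograms",)

    def __init__(self):
        self.histograms: dict[int, _Histogram] = {}

    def histogram(self, context: int) -> _Histogram:
        h = self.histograms.get(context)
        if h is None:
            h = self.histograms[context] = _Histogram()
        return h


def _is_dynamic(context: int) -> bool:
    return CTX_UNCOMPRESSED_U8 < context < STATIC_FULL


class BitWriter:
    """Growable bit buffer + arithmetic-coder state for one block payload."""

    def __init__(self):
        self._buf = bytearray()
        self._nbits = 0
        self._low = 0
        self._high = 0xFFFF
        self._underflow = 0
        self._contexts = _ContextManager()
        self._finished = False

    # -- raw bit plumbing ---------------------------------------------------

    def _emit(self, bit: int) -> None:
        if self._nbits & 7 == 0:
            self._buf.append(0)
        if bit:
            self._buf[-1] |= 1 << (self._nbits & 7)
        self._nbits += 1

    # -- arithmetic coder ---------------------------------------------------

    def _encode(self, cum: int, freq: int, total: int) -> None:
        rng = self._high + 1 - self._low
        self._high = self._low - 1 + rng * (cum + freq) // total
        self._low = self._low + rng * cum // total
        while True:
            if not ((self._high ^ self._low) & _HALF):
                bit = self._low >> 15
                self._emit(bit)
                while self._underflow:
                    self._underflow -= 1
                    self._emit(bit ^ 1)
                self._low = (self._low << 1) & 0xFFFF
                self._high = ((self._high << 1) | 1) & 0xFFFF
            elif (self._low & _QUARTER) and not (self._high & _QUARTER):
                self._underflow += 1
                self._low = (self._low - _QUARTER) << 1
                self._high = (((self._high - _QUARTER) << 1) | 1)
            else:
                return

    def write_symbol(self, context: int, value: int) -> bool:
        """Code one symbol; returns True if the escape path was taken.

        On escape the caller must write the value on an uncompressed channel
        and then call :meth:`add_symbol` — exactly what the
        ``write_compressed_*`` helpers do.
        """
        if self._finished:
            raise U3DEncodeError("writer already finished")
        symbol = value + 1
        escape = False
        if context == CTX_UNCOMPRESSED_U8:
            if not 0 <= value <= 0xFF:
                raise U3DEncodeError(f"u8 channel value out of range: {value}")
            total, cum, freq = 256, value, 1
        elif context >= STATIC_FULL:
            total = context - STATIC_FULL
            if not 0 <= value < total:
                raise U3DEncodeError(
                    f"static context range {total} cannot code {value}")
            cum, freq = value, 1
        else:
            hist = self._contexts.histogram(context)
            total = hist.total
            freq = hist.freq(symbol)
            if freq == 0:
                symbol = 0
                escape = True
                cum, freq = 0, hist.freq(0)
            else:
                cum = hist.cum_below(symbol)
            self._encode(cum, freq, total)
            hist.add(symbol)
            return escape
        self._encode(cum, freq, total)
        return escape

    def add_symbol(self, context: int, value: int) -> None:
        """Register an escaped value in a dynamic context's histogram."""
        if _is_dynamic(context):
            self._contexts.histogram(context).add(value + 1)

    # -- uncompressed channels ---------------------------------------------

    def write_u8(self, value: int) -> None:
        if not 0 <= value <= 0xFF:
            raise U3DEncodeError(f"u8 out of range: {value}")
        # Bit-reversed through the uniform-256 context so that the emitted
        # bit order is LSB first, making aligned bytes verbatim.
        self.write_symbol(CTX_UNCOMPRESSED_U8, _REV8[value])

    def write_u16(self, value: int) -> None:
        if not 0 <= value <= 0xFFFF:
            raise U3DEncodeError(f"u16 out of range: {value}")
        self.write_u8(value & 0xFF)
        self.write_u8(value >> 8)

    def write_u32(self, value: int) -> None:
        if not 0 <= value <= 0xFFFFFFFF:
            raise U3DEncodeError(f"u32 out of range: {value}")
        self.write_u16(value & 0xFFFF)
        self.write_u16(value >> 16)

    def write_u64(self, value: int) -> None:
        if not 0 <= value <= 0xFFFFFFFFFFFFFFFF:
            raise U3DEncodeError(f"u64 out of range: {value}")
        self.write_u32(value & 0xFFFFFFFF)
        self.write_u32(value >> 32)

    def write_f32(self, value: float) -> None:
        self.write_u32(struct.unpack("<I", struct.pack("<f", value))[0])

    def write_string(self, text: str) -> None:
        """Length-prefixed (u16) UTF-8 string."""
        data = text.encode("utf-8")
        if len(data) > 0xFFFF:
            raise U3DEncodeError(
                f"string too long for 16-bit length prefix: {len(data)} bytes")
        self.write_u16(len(data))
        for b in data:
            self.write_u8(b)

    # -- compressed channels -------------------------------------------------

    def _write_compressed(self, context: int, value: int, fallback) -> None:
        if _is_dynamic(context):
            if self.write_symbol(context, value):
                fallback(value)
                self.add_symbol(context, value)
        elif STATIC_FULL <= context < MAX_CONTEXT:
            self.write_symbol(context, value)
        else:
            fallback(value)

    def write_compressed_u32(self, context: int, value: int) -> None:
        self._write_compressed(context, value, self.write_u32)

    def write_compressed_u16(self, context: int, value: int) -> None:
        self._write_compressed(context, value, self.write_u16)

    def write_compressed_u8(self, context: int, value: int) -> None:
        self._write_compressed(context, value, self.write_u8)

    # -- finalization --------------------------------------------------------

    def finish(self) -> bytes:
        """Flush pending coder state, pad to a byte and return the payload."""
        if not self._finished:
            if (self._low, self._high, self._underflow) != (0, 0xFFFF, 0):
                # Pin the final interval so a zero-extended stream decodes.
                self._underflow += 1
                bit = 0 if self._low < _QUARTER else 1
                self._emit(bit)
                while self._underflow:
                    self._underflow -= 1
                    self._emit(bit ^ 1)
            self._finished = True
        return bytes(self._buf)


class BitReader:
    """Decoder mirroring :class:`BitWriter` symbol for symbol.

    Must be driven with the same context sequence the writer used; a
    mismatch desynchronizes the adaptive histograms and typically surfaces
    as a range error here or a structural error in the caller.
    """

    def __init__(self, data: bytes):
        self._data = data
        self._nbits = len(data) * 8
        self._pos = 0               # next bit to pull into the code window
        self._low = 0
        self._high = 0xFFFF
        self._code = 0
        self._contexts = _ContextManager()
        for _ in range(16):
            self._code = (self._code << 1) | self._next_bit()

    def _next_bit(self) -> int:
        p = self._pos
        self._pos += 1
        if p >= self._nbits:
            return 0                # zero fill past the end
        return (self._data[p >> 3] >> (p & 7)) & 1

    def bits_consumed(self) -> int:
        """Upper bound on stream bits examined (includes the 16-bit lookahead)."""
        return min(self._pos, self._nbits)

    def _decode_update(self, cum: int, freq: int, total: int) -> None:
        rng = self._high + 1 - self._low
        self._high = self._low - 1 + rng * (cum + freq) // total
        self._low = self._low + rng * cum // total
        while True:
            if not ((self._high ^ self._low) & _HALF):
                self._low = (self._low << 1) & 0xFFFF
                self._high = ((self._high << 1) | 1) & 0xFFFF
                self._code = ((self._code << 1) & 0xFFFF) | self._next_bit()
            elif (self._low & _QUARTER) and not (self._high & _QUARTER):
                self._low = (self._low - _QUARTER) << 1
                self._high = ((self._high - _QUARTER) << 1) | 1
                self._code = (((self._code - _QUARTER) << 1) & 0xFFFF
                              ) | self._next_bit()
            else:
                return

    def read_symbol(self, context: int) -> tuple[int, bool]:
        """Decode one symbol; returns (value, escaped)."""
        rng = self._high + 1 - self._low
        if context == CTX_UNCOMPRESSED_U8:
            total = 256
            codefreq = ((self._code - self._low + 1) * total - 1) // rng
            value, cum, freq = codefreq, codefreq, 1
            self._decode_update(cum, freq, total)
            return value, False
        if context >= STATIC_FULL:
            total = context - STATIC_FULL
            codefreq = ((self._code - self._low + 1) * total - 1) // rng
            if codefreq >= total:
                raise U3DParseError(
                    f"static context desynchronized (freq {codefreq} of "
                    f"{total})")
            self._decode_update(codefreq, 1, total)
            return codefreq, False
        hist = self._contexts.histogram(context)
        total = hist.total
        codefreq = ((self._code - self._low + 1) * total - 1) // rng
        symbol = hist.find(codefreq)
        cum = hist.cum_below(symbol)
        freq = hist.freq(symbol)
        if freq == 0:
            raise U3DParseError(
                f"dynamic context {context} desynchronized")
        self._decode_update(cum, freq, total)
        hist.add(symbol)
        if symbol == 0:
            return 0, True
        return symbol - 1, False

    def add_symbol(self, context: int, value: int) -> None:
        if _is_dynamic(context):
            self._contexts.histogram(context).add(value + 1)

    # -- uncompressed channels ---------------------------------------------

    def read_u8(self) -> int:
        value, _ = self.read_symbol(CTX_UNCOMPRESSED_U8)
        return _REV8[value]

    def read_u16(self) -> int:
        lo = self.read_u8()
        return lo | (self.read_u8() << 8)

    def read_u32(self) -> int:
        lo = self.read_u16()
        return lo | (self.read_u16() << 16)

    def read_u64(self) -> int:
        lo = self.read_u32()
        return lo | (self.read_u32() << 32)

    def read_f32(self) -> float:
        return struct.unpack("<f", struct.pack("<I", self.read_u32()))[0]

    def read_string(self) -> str:
        n = self.read_u16()
        data = bytes(self.read_u8() for _ in range(n))
        return data.decode("utf-8")

    # -- compressed channels -------------------------------------------------

    def _read_compressed(self, context: int, fallback) -> int:
        if _is_dynamic(context):
            value, escaped = self.read_symbol(context)
            if escaped:
                value = fallback()
                self.add_symbol(context, value)
            return value
        if STATIC_FULL <= context < MAX_CONTEXT:
            value, _ = self.read_symbol(context)
            return value
        return fallback()

    def read_compressed_u32(self, context: int) -> int:
        return self._read_compressed(context, self.read_u32)

    def read_compressed_u16(self, context: int) -> int:
        return self._read_compressed(context, self.read_u16)

    def read_compressed_u8(self, context: int) -> int:
        return self._read_compressed(context, self.read_u8)
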