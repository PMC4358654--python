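"""Tabular point/line import: CSV-like marker lists and connection lists.

Real marker files come in many dialects, so the reader exposes the value
delimiter and the decimal separator (e.g. European ``1,5`` decimals inside
``;``-separated rows) and a row filter for importing only a subset.

Row numbering in error messages is the 1-based physical line number of the
input, so messages point at the line a user sees in an editor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np

from .errors import U3DConfigError, U3DDataError

__all__ = ["RowFilter", "TableReadOptions", "read_marker_list",
           "read_connections", "auto_connect"]


@dataclass
class RowFilter:
    """Keep a subset of data rows.

    A data row with 0-based index ``i`` (counted after comment/blank removal)
    survives iff ``i >= start_row``, ``(i - start_row) % stride == 0``, the
    optional column match holds, and fewer than ``max_rows`` rows have been
    kept so far.
    """

    start_row: int = 0
    max_rows: int | None = None
    stride: int = 1
    match_column: int | None = None
    match_value: str | None = None

    def __post_init__(self):
        if self.start_row < 0:
            raise U3DConfigError("start_row must be >= 0")
        if self.stride < 1:
            raise U3DConfigError("stride must be >= 1")
        if self.max_rows is not None and self.max_rows < 1:
            raise U3DConfigError("max_rows must be >= 1 when set")
        if (self.match_column is None) != (self.match_value is None):
            raise U3DConfigError(
                "match_column and match_value must be set together")


@dataclass
class TableReadOptions:
    delimiter: str = ","
    decimal_separator: str = "."
    comment_prefix: str = "#"
    row_filter: RowFilter = field(default_factory=RowFilter)

    def __post_init__(self):
        if len(self.delimiter) != 1 or len(self.decimal_separator) != 1:
            raise U3DConfigError(
                "delimiter and decimal_separator must be single characters")
        if self.delimiter == self.decimal_separator:
            raise U3DConfigError(
                "delimiter and decimal separator must differ")


def _lines(stream: IO[str] | str | Iterable[str]) -> Iterator[str]:
    if isinstance(stream, str):
        yield from stream.splitlines()
    else:
        for line in stream:
            yield line.rstrip("\r\n")


def _split(line: str, delimiter: str) -> list[str]:
    # A space delimiter treats any whitespace run as one separator.
    if delimiter == " ":
        return [f for f in re.split(r"\s+", line.strip()) if f]
    return [f.strip() for f in line.split(delimiter)]


def _filtered_rows(stream, options: TableReadOptions):
    """Yield (line_number, fields) for rows surviving the filter."""
    filt = options.row_filter
    data_index = 0
    kept = 0
    for lineno, raw in enumerate(_lines(stream), start=1):
        line = raw.strip()
        if not line or (options.comment_prefix
                        and line.startswith(options.comment_prefix)):
            continue
        i = data_index
        data_index += 1
        if i < filt.start_row or (i - filt.start_row) % filt.stride != 0:
            continue
        fields = _split(line, options.delimiter)
        if filt.match_column is not None:
            if filt.match_column >= len(fields):
                continue
            if fields[filt.match_column] != filt.match_value:
                continue
        if filt.max_rows is not None and kept >= filt.max_rows:
            return
        kept += 1
        yield lineno, fields


def _parse_float(field_text: str, options: TableReadOptions,
                 lineno: int, col: int) -> float:
    text = field_text
    if options.decimal_separator != ".":
        if "." in text:
            raise U3DDataError(
                f"unexpected '.' in numeric field {text!r} with decimal "
                f"separator {options.decimal_separator!r}",
                row=lineno, column=col + 1)
        text = text.replace(options.decimal_separator, ".")
    try:
        return float(text)
    except ValueError:
        raise U3DDataError(f"non-numeric field {field_text!r}",
                           row=lineno, column=col + 1) from None


def read_marker_list(stream, options: TableReadOptions | None = None
                     ) -> np.ndarray:
    """Read 3D positions, one per surviving row, in file order.

    Each surviving row must have at least three numeric fields; fields
    beyond the third are ignored (marker files often carry labels or
    timestamps). Returns an (N, 3) float array.
    """
    options = options or TableReadOptions()
    out: list[tuple[float, float, float]] = []
    for lineno, fields in _filtered_rows(stream, options):
        if len(fields) < 3:
            raise U3DDataError(
                f"expected >= 3 fields, found {len(fields)}", row=lineno)
        x, y, z = (_parse_float(fields[c], options, lineno, c)
                   for c in range(3))
        out.append((x, y, z))
    return np.asarray(out, dtype=np.float64).reshape(-1, 3)


def read_connections(stream, options: TableReadOptions | None = None
                     ) -> np.ndarray:
    """Read 0-based edge index pairs, one per surviving row, in file order."""
    options = options or TableReadOptions()
    out: list[tuple[int, int]] = []
    for lineno, fields in _filtered_rows(stream, options):
        if len(fields) < 2:
            raise U3DDataError(
                f"expected >= 2 index fields, found {len(fields)}", row=lineno)
        pair = []
        for col in range(2):
            try:
                value = int(fields[col])
            except ValueError:
                raise U3DDataError(
                    f"non-integer index {fields[col]!r}",
                    row=lineno, column=col + 1) from None
            if value < 0:
                raise U3DDataError(f"negative index {value}",
                                   row=lineno, column=col + 1)
            pair.append(value)
        out.append((pair[0], pair[1]))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def auto_connect(n_positions: int) -> np.ndarray:
    """Chain edges (0,1),(1,2),...,(n-2,n-1); empty for n <= 1.

    This is the automatic rule applied when a line set comes without an
    explicit connection list: each node is joined to the next in order.
    """
    n = int(n_positions)
    if n <= 1:
        return np.zeros((0, 2), dtype=np.int64)
    idx = np.arange(n, dtype=np.int64)
    return np.column_stack([idx[:-1], idx[1:]])
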