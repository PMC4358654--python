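"""Exception and warning types shared across the package."""

from __future__ import annotations


class U3DError(Exception):
    """Base class for all u3dkit errors."""


class U3DConfigError(U3DError):
    """Invalid option combination (e.g. delimiter == decimal separator)."""


class U3DDataError(U3DError):
    """Malformed input data (tables, OBJ, PLY, spec text).

    Carries optional location info so CLI messages can name file/row/column.
    """

    def __init__(self, message: str, *, source: str | None = None,
                 row: int | None = None, column: int | None = None):
        self.source = source
        self.row = row
        self.column = column
        loc = []
        if source is not None:
            loc.append(str(source))
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)


class U3DSpecError(U3DError):
    """Invalid object-specification text or ObjectSpec contents."""


class U3DStructureError(U3DError):
    """Scene-graph structure violation (bad path, dangling reference...)."""


class U3DEncodeError(U3DError):
    """A scene cannot be serialized (empty referenced geometry, overflow...)."""


class U3DParseError(U3DError):
    """A byte stream is not a parseable U3D file (for this reader's subset)."""

    def __init__(self, message: str, *, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at byte offset {offset})"
        super().__init__(message)


class U3DWarning(UserWarning):
    """Non-fatal export issues: dropped degenerates, renamed nodes, etc."""
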