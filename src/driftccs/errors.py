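"""Exception types shared across the package."""


class DriftCCSError(Exception):
    """Base class for all package-specific errors."""


class InsufficientDataError(DriftCCSError, ValueError):
    """Too few observations to determine the requested fit."""


class DegenerateFitError(DriftCCSError, ValueError):
    """The design matrix is rank deficient or the fitted parameters are
    non-physical (e.g. a non-positive mobility slope, which usually means
    mis-ordered or mis-labelled input)."""


class NonPhysicalValueError(DriftCCSError, ValueError):
    """An input violates a physical domain constraint (mass, pressure,
    temperature, mobility ... must be positive)."""


class SchemaError(DriftCCSError, ValueError):
    """A tabular input file does not match the expected schema.

    Carries enough context (file, column, row) to point at the offending
    cell.
    """

    def __init__(self, message: str, *, source: str | None = None,
                 column: str | None = None, row: int | None = None):
        parts = [message]
        if source is not None:
            parts.append(f"file={source!r}")
        if column is not None:
            parts.append(f"column={column!r}")
        if row is not None:
            parts.append(f"row={row}")
        super().__init__("; ".join(parts))
        self.source = source
        self.column = column
        self.row = row
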