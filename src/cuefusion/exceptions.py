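"""Exception hierarchy.

The CLI maps these onto distinct exit codes: configuration/schema problems,
malformed or incomplete data, and statistical degeneracies are reported
separately so batch callers can tell them apart.
"""


class CueFusionError(Exception):
    """Base class for all package errors."""


class InvalidSpecificationError(CueFusionError):
    """A stimulus, observer or design specification violates its invariants."""


class SchemaError(InvalidSpecificationError):
    """A configuration file is malformed; carries the offending field path."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"config field '{field}': {message}")


class GeometryError(CueFusionError):
    """A projection is undefined (point behind an eye, ray parallel to plane)."""


class DataError(CueFusionError):
    """A trial table is malformed."""


class IncompleteDataError(DataError):
    """A subject's trials do not cover the analysed conditions."""


class DegenerateDataError(CueFusionError):
    """A statistical procedure is undefined on these data (zero variance)."""
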