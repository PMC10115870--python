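"""Exception hierarchy shared across the package."""


class DysmapError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(DysmapError, ValueError):
    """A caller-supplied argument violates a precondition."""


class FormatError(DysmapError, ValueError):
    """A file on disk does not conform to the expected format."""


class ParseError(FormatError):
    """A tabular input failed to parse; carries the offending row when known."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class OutOfBoundsError(DysmapError, ValueError):
    """A world coordinate falls outside the analysis grid."""


class DegenerateDesignError(DysmapError, ValueError):
    """The design matrix cannot support the requested inference."""


class UnmappableSeedError(DysmapError, ValueError):
    """A stimulation locus has no connectome node within the distance cutoff."""


class ConfigError(DysmapError, ValueError):
    """A run configuration is invalid (unknown keys, bad values)."""
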