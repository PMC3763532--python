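"""Exception types raised by mirclust."""


class MirclustError(Exception):
    """Base class for all package-specific errors."""


class GFF3ParseError(MirclustError):
    """A GFF3 file could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class TreeError(MirclustError):
    """A species tree violates the rooted/named-lineage contract."""


class HomologyError(MirclustError):
    """A locus or family is missing from the homology map."""


class FixtureError(MirclustError):
    """The packaged fixture failed an internal consistency check."""
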