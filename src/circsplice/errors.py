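"""Exception hierarchy shared across the package."""


class CircSpliceError(Exception):
    """Base class for all package-specific errors."""


class InvalidAlphabet(CircSpliceError):
    """A sequence contains a character outside {A,C,G,T,U,N} (any case)."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(f"invalid character {char!r} at position {position}")


class LengthMismatch(CircSpliceError):
    """A sequence does not have the required length."""


class FlankTooShort(CircSpliceError):
    """An intron or exon flank is shorter than the 50-nt minimum."""


class ParseError(CircSpliceError):
    """A dataset file is malformed; carries the offending record number."""

    def __init__(self, message: str, record: int | None = None):
        self.record = record
        if record is not None:
            message = f"{message} (record {record})"
        super().__init__(message)


class InfeasibleSplit(CircSpliceError):
    """Requested k-fold split cannot be satisfied by the dataset."""


class InfeasiblePlant(CircSpliceError):
    """A motif plant cannot fit inside its designated window side."""


class DegenerateLabels(CircSpliceError):
    """Training set contains only one class."""


class ArchitectureInfeasible(CircSpliceError):
    """A layer in the configured network would have non-positive length."""


class NoSupport(CircSpliceError):
    """A filter has no qualifying subsequences, so no PPM can be built."""


class NoOccurrences(CircSpliceError):
    """An occurrence-based statistic was requested on zero occurrences."""
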