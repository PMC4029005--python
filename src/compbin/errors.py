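"""Exception types shared across the package."""


class CompbinError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CompbinError, ValueError):
    """A parameter is outside its documented range or otherwise invalid."""


class UndefinedValueError(CompbinError, ValueError):
    """The requested quantity is mathematically undefined for this input
    (e.g. GC fraction of a sequence with no A/C/G/T bases)."""


class EmptyInputError(CompbinError, ValueError):
    """An operation received an empty input set where at least one item
    is required (e.g. no contigs survive a length filter)."""


class DegenerateThresholdError(CompbinError, ValueError):
    """A threshold produced a degenerate result (e.g. zero valley neurons
    when extracting clusters from a U-matrix)."""


class FastaParseError(CompbinError, ValueError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
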