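"""Exception types shared across the pipeline."""


class TiercallError(Exception):
    """Base class for all tiercall errors."""


class ParseError(TiercallError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class UnknownChromosomeError(TiercallError):
    """A record references a chromosome absent from the loaded genome."""


class CoordinateError(TiercallError):
    """A coordinate falls outside the bounds of its chromosome."""


class SizingError(TiercallError):
    """Requested synthetic layout does not fit in the genome."""


class NormalizationError(TiercallError):
    """Size factors cannot be computed from the given count matrix."""


class QCError(TiercallError):
    """Too little data survives the QC filters."""


class InputError(TiercallError):
    """Invalid argument or inconsistent inputs."""
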