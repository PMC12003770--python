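"""Exception hierarchy.

Everything raised on purpose derives from :class:`ResectSeqError` so callers
(and the CLI) can distinguish anticipated analysis failures from bugs.
"""


class ResectSeqError(Exception):
    """Base class for all package errors."""


class ValidationError(ResectSeqError):
    """An input violates a documented precondition."""


class ParseError(ResectSeqError):
    """A text input file could not be parsed.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)


class BoundsError(ResectSeqError):
    """A genomic coordinate falls outside the genome."""


class DegenerateProfileError(ResectSeqError):
    """A statistic is undefined because the relevant signal window is empty."""


class CalibrationError(ResectSeqError):
    """Simulator tract-distribution calibration failed or is infeasible."""


class UndefinedPeriodError(ResectSeqError):
    """No periodicity is detectable in an oligo-length histogram."""
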