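"""Exception hierarchy shared across the pipeline."""


class CondynError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CondynError, ValueError):
    """A parameter violates its documented precondition."""


class FormatError(CondynError, ValueError):
    """An input file or array does not match the expected format."""


class DegenerateInputError(CondynError, ValueError):
    """Input is structurally valid but mathematically degenerate (e.g. log of a zero MSD)."""


class ShortTrajectoryError(InvalidParameterError):
    """Trajectory shorter than the analysis window requires."""


class UndefinedDistanceError(CondynError, ValueError):
    """Distance query against an empty boundary set."""
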