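"""Exception hierarchy for the spastiq pipeline."""


class SpastiqError(Exception):
    """Base class for all package errors."""


class FormatError(SpastiqError, ValueError):
    """A trial file does not have the expected layout (missing columns, no header)."""


class ParseError(SpastiqError, ValueError):
    """A trial file contains a cell that cannot be parsed as a number."""


class ConfigError(SpastiqError, ValueError):
    """Invalid configuration (filter bands past Nyquist, non-positive widths, ...)."""


class InputError(SpastiqError, ValueError):
    """An input array violates a precondition (too short, wrong shape, ...)."""


class OnsetNotFoundError(InputError):
    """A trajectory never satisfies the angle-onset double threshold."""


class DegenerateFitError(SpastiqError, ValueError):
    """A regression problem is degenerate (all velocities identical, constant target, ...)."""


class UnsupportedLabelError(SpastiqError, ValueError):
    """A MAS label outside the supported {0, 1, 1+, 2} range."""
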