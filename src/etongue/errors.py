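"""Exception hierarchy for the etongue package."""


class EtongueError(Exception):
    """Base class for all package-specific errors."""


class InputError(EtongueError, ValueError):
    """Invalid user-supplied value (negative concentration, empty series, ...)."""


class ConfigError(EtongueError, ValueError):
    """A configuration file or object violates its contract."""


class ModelError(EtongueError):
    """The physical model cannot be evaluated (e.g. log of a non-positive argument)."""


class EstimationError(EtongueError):
    """A characterization estimator cannot identify its quantity from the data."""


class ConvergenceError(EtongueError):
    """Iterative training failed to make progress on a solvable problem."""


class ParseError(EtongueError, ValueError):
    """A data file could not be parsed; the message carries file and line context."""
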