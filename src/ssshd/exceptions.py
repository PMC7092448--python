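"""Exception hierarchy shared across the package."""


class SsshdError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SsshdError, ValueError):
    """Malformed data: non-finite values, single-class labels, shape errors."""


class InsufficientDataError(InvalidInputError):
    """A class has too few samples for the requested statistic."""


class ParameterError(SsshdError, ValueError):
    """A tuning or configuration parameter is out of its admissible range."""


class NoInformativeFitError(SsshdError, RuntimeError):
    """Every candidate model in a tuning sweep was degenerate (beta = 0)."""
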