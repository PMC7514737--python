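"""Exception types shared across the package."""


class AipidError(Exception):
    """Base class for package-specific errors."""


class InvalidParameterError(AipidError, ValueError):
    """A parameter is outside its admissible range."""


class DimensionMismatchError(AipidError, ValueError):
    """Generalised-coordinate operands have incompatible embedding orders."""


class InvalidInputError(AipidError, ValueError):
    """An input value is non-finite or otherwise malformed."""


class NumericalInstabilityError(AipidError, RuntimeError):
    """The explicit-Euler recognition dynamics diverged.

    Raised loudly rather than silently retrying with a smaller step; the
    message names the embedding order whose expectation left the
    configured bound.
    """


class NoRecoveryError(AipidError, RuntimeError):
    """The velocity never re-entered the target band after a disturbance."""


class UnknownScenarioError(AipidError, KeyError):
    """A scenario name is not one of the registered experiments."""
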