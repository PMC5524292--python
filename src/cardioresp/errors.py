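"""Exception types shared across the package."""


class CardiorespError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CardiorespError, ValueError):
    """A model parameter violates its physical constraints."""


class InvalidInputError(CardiorespError, ValueError):
    """A computed-quantity input is outside its admissible range."""


class IntegrationError(CardiorespError, RuntimeError):
    """The ODE integration produced non-finite state values."""


class SteadyStateTimeout(CardiorespError, RuntimeError):
    """A protocol phase failed to reach steady state within its budget."""


class ConfigError(CardiorespError, ValueError):
    """A scenario configuration document failed validation."""
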