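"""Exception hierarchy for decayamp.

All errors derive from :class:`DecayAmpError` so callers can catch the
package's failures with a single clause; each subclass also derives from
the closest builtin (``ValueError``/``RuntimeError``) for idiomatic use.
"""


class DecayAmpError(Exception):
    """Base class for all decayamp errors."""


class ConfigurationError(DecayAmpError, ValueError):
    """A parameter object or config file is invalid (bad key, bad range)."""


class DomainError(DecayAmpError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class IntegrationError(DecayAmpError, RuntimeError):
    """The state became non-finite during numerical integration."""


class InputError(DecayAmpError, ValueError):
    """Mismatched or incomplete inputs to an analysis operation."""


class DegenerateRegimeError(DecayAmpError, ValueError):
    """The requested analytic quantity does not exist in this regime."""
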