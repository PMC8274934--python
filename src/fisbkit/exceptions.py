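"""Exception hierarchy shared across fisbkit modules."""


class FisbkitError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FisbkitError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigurationError(FisbkitError, ValueError):
    """An invalid option, grid specification or config file."""


class NoSolutionError(FisbkitError, RuntimeError):
    """A root/solution provably does not exist in the searched bracket.

    Distinct from :class:`ConvergenceError`: here the absence of a solution
    is the answer, not a numerical failure.
    """


class NoTransitionError(NoSolutionError):
    """An open/closed transition was not bracketed (no sign change)."""


class ConvergenceError(FisbkitError, RuntimeError):
    """An iterative solver failed although a solution is believed to exist."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class DataError(FisbkitError, ValueError):
    """Input data violate a schema or a physical constraint."""


class UnidentifiableFitError(FisbkitError, ValueError):
    """The data carry no information about the parameter being fitted."""
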