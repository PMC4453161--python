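"""Exception hierarchy for porecond."""


class PorecondError(Exception):
    """Base class for all porecond errors."""


class InvalidParameterError(PorecondError, ValueError):
    """A physical parameter is outside its admissible range."""


class ConfigurationError(PorecondError, ValueError):
    """Inconsistent or incomplete configuration (e.g. a missing table)."""


class DegenerateInputError(PorecondError, ValueError):
    """Input is structurally valid but degenerate for the requested operation."""


class NumericalError(PorecondError, RuntimeError):
    """An iterative numerical procedure failed to converge.

    Carries diagnostic state (last residual, tail estimate, iteration trace)
    in ``details`` when available.
    """

    def __init__(self, message, **details):
        super().__init__(message)
        self.details = details


class EmptyPoreError(PorecondError):
    """No bin of a radial profile exceeds the occupancy threshold (dewetted pore)."""
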