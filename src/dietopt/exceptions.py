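"""Exception hierarchy for dietopt.

All library errors derive from :class:`DietOptError` so callers (and the CLI)
can map them onto exit codes without inspecting messages.
"""


class DietOptError(Exception):
    """Base class for all dietopt errors."""


class SchemaError(DietOptError):
    """An input table/config is missing a required column or key."""


class ValidationError(DietOptError):
    """A value violates a domain invariant (negative density, bad weight sum, ...)."""


class UnknownProductError(DietOptError, KeyError):
    """A diet references a product id absent from the food database."""


class NormalizationError(DietOptError):
    """A normalization context cannot be built (e.g. all-zero maxima)."""


class InfeasibleError(DietOptError):
    """A constraint set admits no feasible diet."""

    def __init__(self, message: str, report: dict | None = None):
        super().__init__(message)
        self.report = report or {}


class SolverError(DietOptError):
    """The NLP solver failed to converge from every starting point."""


class UnaffordableDietError(DietOptError):
    """Diet cost meets or exceeds the available consumption income."""
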