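"""Exception and warning types shared across the package."""


class CBCTrendError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CBCTrendError):
    """A field in an input table could not be parsed; names the offending row."""


class ValidationError(CBCTrendError):
    """An input violated a dataset invariant (negative count, duplicate row, ...)."""


class RegionAssignmentError(CBCTrendError):
    """A circle matched no rule in the region rule table."""


class EmptyDatasetError(CBCTrendError):
    """Filtering removed every circle; downstream analysis is impossible."""


class UnidentifiableModelError(CBCTrendError):
    """The dataset cannot identify the model (e.g. a single circle or year)."""


class ConvergenceError(CBCTrendError):
    """Raised by the pipeline when a fit fails its convergence checks."""


class DiagnosticError(CBCTrendError):
    """Convergence diagnostics requested on an unsuitable set of draws."""


class ExtrapolationError(CBCTrendError):
    """A derived quantity was requested outside the fitted region-year range."""


class AllocationWarning(UserWarning):
    """No identified birds anywhere in the fallback chain; counts left unresolved."""
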