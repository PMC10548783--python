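"""Exception types shared across the pipeline."""


class MTConformError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MTConformError, ValueError):
    """An input file violates the expected format or its invariants."""


class InsufficientDataError(MTConformError, ValueError):
    """Too few usable data points for the requested computation."""


class FitFailureError(MTConformError, RuntimeError):
    """The optimizer (or too many Monte-Carlo refits) failed."""
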