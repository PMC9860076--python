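"""Exception hierarchy shared across the package."""


class GermLayerTrackerError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(GermLayerTrackerError, ValueError):
    """A file could not be parsed or violated a value/uniqueness invariant.

    The message always names the offending row/column or cell.
    """


class ValidationError(GermLayerTrackerError, ValueError):
    """An in-memory object violated an invariant (range, coverage, class vocabulary)."""


class UnderdeterminedError(GermLayerTrackerError, ValueError):
    """A least-squares system has fewer usable equations than unknowns."""
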