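"""Exception types shared across the mapper."""


class GramMapError(Exception):
    """Base class for all grammap errors."""


class InvalidParameterError(GramMapError, ValueError):
    """A parameter violates a documented precondition (e.g. q <= 0)."""


class NotEnoughGramsError(GramMapError):
    """A read cannot supply the requested number of non-overlapping grams.

    Raised by gram selection; callers fall back to a weaker filter path.
    """


class ParseError(GramMapError, ValueError):
    """A sequence file is malformed; the message carries the location."""
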