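"""Exception hierarchy shared across the package."""


class DelimError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(DelimError):
    """Malformed alignment: unequal lengths, duplicate ids, empty input."""


class ParseError(DelimError):
    """Unreadable input file or illegal character."""


class SaturationError(DelimError):
    """A distance correction is undefined for the observed proportions."""


class TreeError(DelimError):
    """Invalid or non-ultrametric input tree."""


class OptimizationError(DelimError):
    """Likelihood optimizer failed to converge."""
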