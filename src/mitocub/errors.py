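"""Exception hierarchy.

Everything raised on purpose derives from :class:`MitocubError` so callers
(and the CLI) can distinguish computation failures from bugs.
"""


class MitocubError(Exception):
    """Base class for all mitocub errors."""


class ParseError(MitocubError):
    """Malformed input file."""


class CoordinateError(MitocubError):
    """Feature interval outside the sequence bounds."""


class ExtractionError(MitocubError):
    """A coding sequence could not be extracted cleanly."""


class FrameError(ExtractionError):
    """Internal stop codon in what should be an open reading frame."""


class EmptySelectionError(MitocubError):
    """A gene-set query matched no features."""


class UndefinedStatisticError(MitocubError):
    """A statistic's denominator is zero (skew, PR2 axis, pi)."""


class InsufficientDataError(MitocubError):
    """Too few points/rows for the requested analysis."""


class ConfigError(MitocubError):
    """Inconsistent analysis parameters (e.g. hi <= lo)."""


class FeasibilityError(MitocubError):
    """Simulation targets that cannot be realised."""
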