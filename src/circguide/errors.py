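"""Exception hierarchy for circguide.

Every error raised on a user-facing path derives from :class:`CircguideError`
so the CLI can map failures to exit code 1 while argument/usage problems
stay with click's exit code 2.
"""


class CircguideError(Exception):
    """Base class for all circguide errors."""


class PartError(CircguideError):
    """A part is missing, malformed, or inconsistent with its declared role."""


class GrammarError(CircguideError):
    """Inputs violate the grammar of the requested cassette variant."""


class AlphabetError(CircguideError):
    """Sequence contains characters outside the expected alphabet."""


class FoldingError(CircguideError):
    """Invalid input to a structure-prediction routine."""


class EngineUnavailableError(CircguideError):
    """A configured external structure-prediction engine cannot be run."""


class EngineOutputError(CircguideError):
    """External engine produced output that cannot be parsed."""


class ScreenError(CircguideError):
    """Invalid screening configuration or library request."""


class QuantifyError(CircguideError):
    """Invalid input to an editing-outcome statistic."""


class FormatError(CircguideError):
    """A file could not be parsed in the expected format."""
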