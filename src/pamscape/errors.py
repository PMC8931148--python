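"""Exception hierarchy.

Everything raised on purpose by pamscape derives from :class:`PamscapeError`,
so callers can catch one type at a workflow boundary.
"""


class PamscapeError(Exception):
    """Base class for all pamscape errors."""


class AlphabetError(PamscapeError):
    """A sequence or code contains characters outside the allowed alphabet."""


class ParameterError(PamscapeError, ValueError):
    """A numeric or structural parameter is out of its documented range."""


class UnsupportedMotifError(PamscapeError):
    """The requested operation needs a motif property this motif lacks."""


class ConsistencyError(PamscapeError):
    """Inputs that must agree (sites vs. record, equal lengths) do not."""


class DataError(PamscapeError):
    """Input data contradicts the reference it is declared against."""


class PlacementError(PamscapeError):
    """A synthetic construct could not be placed after bounded retries."""
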