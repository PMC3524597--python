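"""Exception hierarchy shared by all pipeline stages."""


class GreenWallCbaError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(GreenWallCbaError, ValueError):
    """A numeric parameter violates its domain (e.g. non-positive rate)."""


class MissingIndexError(GreenWallCbaError, LookupError):
    """A consumer price index is not available for a requested year."""


class MissingRateError(GreenWallCbaError, LookupError):
    """An exchange rate is not available for a (currency, year) pair."""


class ZeroUncertaintyError(GreenWallCbaError, ValueError):
    """A degenerate uncertainty statement would imply an infinite weight."""


class UndefinedRatioError(GreenWallCbaError, ZeroDivisionError):
    """A ratio is requested whose denominator is zero."""


class ValidationError(GreenWallCbaError, ValueError):
    """An input record or file failed schema/invariant validation.

    ``context`` carries a human-readable location (row index, field name,
    file path) so CLI users can find the offending input.
    """

    def __init__(self, message: str, context: str | None = None):
        self.context = context
        super().__init__(f"{context}: {message}" if context else message)


class UnknownFixtureError(GreenWallCbaError, KeyError):
    """An unknown packaged-fixture name was requested."""
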