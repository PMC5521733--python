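"""Package-wide exception types."""


class TevTradeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TevTradeError):
    """An invalid configuration value; the message names the offending field."""


class ScreeningError(TevTradeError):
    """Record screening removed every record."""


class GeometryError(TevTradeError):
    """Two gridded inputs do not share the same geometry."""


class FitError(TevTradeError):
    """A model could not be fitted (e.g. rank-deficient design)."""
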