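"""Exception hierarchy shared across the package."""


class CndcError(Exception):
    """Base class for all package-specific errors."""


class WeatherDataError(CndcError):
    """Malformed or incomplete hourly weather input (gaps, partial days)."""


class SchemaError(CndcError):
    """A CSV or config file does not match its documented schema."""


class FitError(CndcError):
    """A model fit could not be performed (too few points, no convergence)."""


class ConfigError(CndcError):
    """Invalid or incomplete configuration (e.g. unset plant density)."""
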