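"""Package exception types."""


class RedalphaError(Exception):
    """Base class for package errors."""


class ConfigurationError(RedalphaError, ValueError):
    """Invalid model, parameter, or configuration value."""


class FormatError(RedalphaError, ValueError):
    """Unparseable or empty input file."""


class GeometryError(RedalphaError, ValueError):
    """Degenerate coordinate geometry (coincident or collinear points)."""
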