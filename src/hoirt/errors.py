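"""Exception types shared across the package."""


class HoirtError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(HoirtError, ValueError):
    """A parameter value violates its domain (e.g. non-positive discrimination)."""


class ShapeError(HoirtError, ValueError):
    """Arrays passed together are dimensionally inconsistent."""


class ConfigurationError(HoirtError, ValueError):
    """A run configuration is invalid (e.g. no anchor group, empty dimension)."""
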