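"""Exception hierarchy shared across the package."""


class MorphodivergeError(Exception):
    """Base class for all package errors."""


class ParseError(MorphodivergeError):
    """A landmark or table file could not be parsed."""


class ValidationError(MorphodivergeError):
    """Input data violate a structural invariant."""


class DegenerateConfigurationError(MorphodivergeError):
    """A landmark configuration is degenerate (e.g. zero centroid size)."""
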