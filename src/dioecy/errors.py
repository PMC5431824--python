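"""Exception hierarchy shared across the package."""


class DioecyError(Exception):
    """Base class for all package errors."""


class ConfigError(DioecyError):
    """A configuration value is missing, non-finite or out of range."""


class StructuralError(DioecyError):
    """An input container violates a structural invariant (empty matrix,
    duplicate ids, mismatched shapes)."""


class ParseError(DioecyError):
    """A file could not be parsed as the declared format."""


class ModelError(DioecyError):
    """A statistical model could not be constructed or compared
    (rank deficiency, non-nested comparison, missing design cells)."""
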