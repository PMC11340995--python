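"""Exception hierarchy shared across the package."""


class ScharmError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ScharmError, ValueError):
    """An on-disk file violates the expected format or an invariant."""


class DimensionError(ScharmError, ValueError):
    """Shapes or parcellations of two objects do not match."""


class DesignError(ScharmError, ValueError):
    """A statistical design is invalid (rank-deficient, unbalanced, ...)."""
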