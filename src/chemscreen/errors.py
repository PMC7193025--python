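"""Exception hierarchy shared across the package."""


class ChemscreenError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ChemscreenError, ValueError):
    """A table is missing a required column or has an invalid header."""


class ParseError(ChemscreenError, ValueError):
    """A line or field could not be parsed; message carries the location."""


class ValidationError(ChemscreenError, ValueError):
    """Parsed content violates a domain invariant (duplicates, ranges...)."""


class DegenerateModelError(ChemscreenError, ValueError):
    """A gene model has no usable variance (w'Lw below tolerance)."""
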