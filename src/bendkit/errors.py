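"""Exception hierarchy shared across the toolkit."""


class BendkitError(Exception):
    """Base class for all package errors."""


class ParseError(BendkitError):
    """A coordinate file could not be parsed."""


class EmptyModelError(BendkitError):
    """A parsed file contained no protein chains."""


class FormatError(BendkitError):
    """A model cannot be represented in the requested output format."""


class SelectionError(BendkitError):
    """An atom selection referenced chains or residues that do not exist."""


class AnnotationError(BendkitError):
    """Chain classification or residue mapping failed."""


class GeometryError(BendkitError):
    """A geometric operation received degenerate or insufficient input."""


class ConfigurationError(BendkitError):
    """Missing or inconsistent configuration data (e.g. unknown element radius)."""


class FitError(BendkitError):
    """Nonlinear fitting failed to converge or was unidentifiable."""
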