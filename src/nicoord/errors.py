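"""Exception hierarchy shared across the package."""


class NicoordError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NicoordError, ValueError):
    """A file violates the expected fixed-column or record layout."""


class EmptyInputError(NicoordError, ValueError):
    """An input file or collection contained no usable records."""


class ValidationError(NicoordError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateGeometryError(NicoordError, ValueError):
    """Vectors required for an angle/torsion are of zero length."""


class NotClassifiableError(NicoordError, ValueError):
    """Too few donor atoms to assign a coordination geometry."""


class InsufficientDataError(NicoordError, ValueError):
    """Fewer observations than the statistic requires."""


class PatternSyntaxError(NicoordError, ValueError):
    """A PROSITE pattern string does not parse.

    Carries ``offset``, the 0-based character index of the first
    offending character.
    """

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset
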