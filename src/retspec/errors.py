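"""Exception hierarchy shared across the package."""


class RetspecError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RetspecError, ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(RetspecError, ValueError):
    """A file could not be parsed; message names the offending line."""


class EmptyInputError(ValidationError):
    """A file or collection that must be non-empty was empty."""


class SelectionError(RetspecError, ValueError):
    """An atom selection resolved to the wrong number of atoms."""


class SingularityError(RetspecError, ArithmeticError):
    """Potential evaluation requested at (or too close to) a point charge."""


class RankDeficiencyError(RetspecError, ArithmeticError):
    """Charge-fit normal equations are singular; message names the atoms."""


class DegenerateSpectrumError(RetspecError, ValueError):
    """An operation received a flat/degenerate spectrum summary."""
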