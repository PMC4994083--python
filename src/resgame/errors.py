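"""Exception hierarchy for resgame."""


class ResgameError(Exception):
    """Base class for all resgame errors."""


class InvalidParameterError(ResgameError, ValueError):
    """A model parameter or operation input violates its contract."""


class ConfigurationError(ResgameError, ValueError):
    """A run configuration file or field is invalid."""


class InternalConsistencyError(ResgameError, RuntimeError):
    """Model state reached a condition that should be impossible."""


class NumericalDegeneracyError(ResgameError, FloatingPointError):
    """All fitness weights underflowed to zero; rescale payoffs (smaller w)."""
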