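"""Exception types raised across the package."""


class RollfishError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RollfishError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidInputError(RollfishError, ValueError):
    """An input object is malformed (wrong shape, alphabet, label set...)."""


class InsufficientDataError(RollfishError, ValueError):
    """Too few observations to compute the requested statistic."""


class DegenerateLabelsError(RollfishError, ValueError):
    """A classification task received only one class."""


class UndefinedCorrelationError(RollfishError, ValueError):
    """Correlation requested on a constant vector."""


class CapacityError(RollfishError, RuntimeError):
    """A design request exceeds what the input can host.

    Carries ``achievable``, the number of design units that could be placed.
    """

    def __init__(self, message: str, achievable: int = 0):
        super().__init__(message)
        self.achievable = achievable


class ExhaustionError(RollfishError, RuntimeError):
    """A randomized search ran out of candidates without success."""
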