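"""Exception hierarchy for irtkit."""


class IRTError(Exception):
    """Base class for all irtkit errors."""


class ThermalIOError(IRTError):
    """Raised when a temperature map cannot be parsed."""


class DimensionError(IRTError):
    """Raised when array shapes disagree with declared geometry or each other."""


class GeometryError(IRTError):
    """Raised when a silhouette or shift does not fit inside the frame."""


class LandmarkNotFoundError(IRTError):
    """Raised when no neck landmark can be detected (empty foreground)."""


class DomainError(IRTError):
    """Raised when a point lies outside a deformation model's domain."""


class OptimizationDivergedError(IRTError):
    """Raised when the registration metric becomes non-finite.

    Carries the partial convergence trace in ``trace``.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class PolygonError(IRTError):
    """Raised for degenerate, self-intersecting or out-of-frame polygons."""


class EmptyROIError(IRTError):
    """Raised when statistics are requested over an empty mask."""


class DegenerateROIError(IRTError):
    """Raised when a mask is too thin to support gradient estimates."""


class UndefinedDiceError(IRTError):
    """Raised when the Dice coefficient is undefined (both masks empty)."""


class InputError(IRTError):
    """Raised for malformed batch/agreement inputs (counts, empty lists)."""
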