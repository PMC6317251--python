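"""Exception types shared across the package."""


class ParenchymaSegError(Exception):
    """Base class for all package-specific errors."""


class VolumeIOError(ParenchymaSegError, IOError):
    """A volume or mask could not be read or written."""


class ShapeError(ParenchymaSegError, ValueError):
    """Arrays have inconsistent or unexpected shapes."""


class GridError(ParenchymaSegError, ValueError):
    """Slice dimensions are not divisible by the requested patch size."""


class GeometryError(ParenchymaSegError, ValueError):
    """Phantom geometry violates its invariants (e.g. lung outside body)."""


class DegenerateInputError(ParenchymaSegError, ValueError):
    """Input admits no meaningful solution (e.g. all values identical)."""


class BalanceError(ParenchymaSegError, ValueError):
    """Not enough negative candidates to balance the positive class."""


class UndefinedMetricError(ParenchymaSegError, ZeroDivisionError):
    """A metric's denominator is zero or an operand is empty."""


class SegmentationFailure(ParenchymaSegError, RuntimeError):
    """The pipeline produced an unusable (empty) mask."""
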