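"""Exception hierarchy.

Every error raised by the package derives from :class:`CranioflowError`,
so callers can catch one type at pipeline boundaries while tests assert
the specific failure mode.
"""


class CranioflowError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(CranioflowError, ValueError):
    """A phantom/acquisition specification violates its invariants."""


class GeometryError(CranioflowError, ValueError):
    """Vessel geometry is infeasible (overlap, out of grid, too thin)."""


class DegenerateSeedError(CranioflowError, ValueError):
    """A segmentation seed pixel has zero temporal variance."""


class EmptySegmentationError(CranioflowError, ValueError):
    """No pixel (or too small a region) passes the correlation threshold."""


class BoundsError(CranioflowError, ValueError):
    """A mask does not fit the image it is applied to."""


class DegenerateInputError(CranioflowError, ValueError):
    """A quantity required to be positive (tCBF, mean venous flow, PTP-PG) is not."""


class AlignmentError(CranioflowError, ValueError):
    """Waveforms are not on a common phase grid."""


class EmptyInputError(CranioflowError, ValueError):
    """A statistical routine received no usable (non-missing) data."""


class UndefinedStatisticError(CranioflowError, ValueError):
    """A statistic is undefined for the input (e.g. zero-variance ranks)."""


class ConfigurationError(CranioflowError, ValueError):
    """A run configuration references missing files or invalid settings."""


class IntegrityError(CranioflowError, RuntimeError):
    """A packaged fixture failed its checksum."""
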