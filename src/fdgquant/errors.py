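"""Exception hierarchy for the pipeline.

Every error raised deliberately by fdgquant derives from :class:`FdgQuantError`
so callers can catch pipeline problems without masking programming errors.
"""


class FdgQuantError(Exception):
    """Base class for all fdgquant errors."""


class ValidationError(FdgQuantError, ValueError):
    """A domain object violates one of its invariants."""


class FormatError(FdgQuantError):
    """An on-disk artifact does not match the expected layout."""


class GridMismatchError(FdgQuantError):
    """A mask and an image do not share the same voxel grid."""


class EmptyVoiError(FdgQuantError):
    """A referenced VOI label covers zero voxels."""


class UnknownOrganError(FdgQuantError, KeyError):
    """An organ name has no label in the mask's name table."""


class ParameterError(FdgQuantError, ValueError):
    """A model parameter set violates its constraints."""


class UnitError(FdgQuantError):
    """An operation received a curve in the wrong units."""


class InsufficientDataError(FdgQuantError):
    """Too few data points to perform the requested fit."""


class DegenerateInputError(FdgQuantError):
    """Input values make the operation ill-defined (e.g. zero plasma activity)."""


class SingularFitError(FdgQuantError):
    """The regression design is singular (no variance in the regressor)."""


class MissingDataError(FdgQuantError):
    """A required measurement is absent."""


class ConfigError(FdgQuantError):
    """A simulation or CLI configuration is inconsistent."""
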