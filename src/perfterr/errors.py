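"""Exception hierarchy for perfterr.

All package errors derive from :class:`PerfterrError` so callers can catch
pipeline failures without masking programming errors.
"""


class PerfterrError(Exception):
    """Base class for all perfterr errors."""


class FormatError(PerfterrError):
    """A file could not be parsed as the expected format."""


class DimensionalityError(FormatError):
    """An image does not have the required number of dimensions."""


class ValidationError(PerfterrError):
    """Data violates an invariant (non-finite voxels, empty masks, ...)."""


class ManifestError(PerfterrError):
    """A specimen or cohort manifest is malformed or inconsistent."""


class CongruenceError(PerfterrError):
    """Two grids that must share shape and spacing do not."""


class GridError(PerfterrError):
    """A phantom grid is too small to host the region layout."""


class LowControlSignalError(PerfterrError):
    """Control-hip enhancement at or below the configured floor (strict QC)."""
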