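"""Exception hierarchy shared across the package."""


class CbctQaError(Exception):
    """Base class for all package-specific errors."""


class InvalidProtocolError(CbctQaError, ValueError):
    """A protocol violates its invariants (non-positive speed, bad trajectory, ...)."""


class FormatError(CbctQaError, ValueError):
    """An input table is malformed (missing column, empty, unparseable value)."""


class IncompleteReadingsError(CbctQaError, ValueError):
    """A chamber reading set is missing positions required by the trajectory."""


class GeometryError(CbctQaError, ValueError):
    """An ROI or layout element falls outside the volume or overlaps illegally."""


class TooSmallRoiError(GeometryError):
    """An ROI selects fewer voxels than the minimum required for stable statistics."""


class ConfigurationError(CbctQaError, ValueError):
    """An analysis configuration is unusable (e.g. too few ROIs per row)."""


class DetectionError(CbctQaError, ValueError):
    """A bead (or other expected feature) could not be located in the volume."""


class DegenerateDataError(CbctQaError, ValueError):
    """A statistic is undefined on the given data (zero variance, empty group, ...)."""
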