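"""Exception hierarchy for the package."""


class SvdMarkersError(Exception):
    """Base class for all package errors."""


class ConfigError(SvdMarkersError):
    """An invalid configuration field; the message names the field."""


class ShapeError(SvdMarkersError):
    """Volumes that should share a grid do not; the message names the volume."""


class EmptyMaskError(SvdMarkersError):
    """A tissue class contains no voxels (before or after cleaning)."""


class GenerationError(SvdMarkersError):
    """The phantom generator cannot honour the requested geometry."""


class NormLookupError(SvdMarkersError):
    """An age falls outside the supported range of the normative table."""


class DegenerateDataError(SvdMarkersError):
    """A statistic is undefined on the given data (e.g. zero variance)."""


class CollinearityError(SvdMarkersError):
    """The regression design matrix is rank deficient."""


class SampleSizeError(SvdMarkersError):
    """Too few observations for the requested model."""
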