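"""Exception hierarchy shared across the pipeline stages."""


class CTMorphError(Exception):
    """Base class for all ctmorph errors."""


class ConfigurationError(CTMorphError, ValueError):
    """Invalid parameter combination (bad window, missing voxel size, ...)."""


class SizingError(CTMorphError, ValueError):
    """A requested structure or operation does not fit the volume."""


class FormatError(CTMorphError, ValueError):
    """Malformed input data (e.g. TIFF slices of unequal shape)."""


class EmptyDomainError(CTMorphError, ValueError):
    """An operation that needs a nonempty voxel set received an empty one."""
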