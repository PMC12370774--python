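"""Exception hierarchy shared across the pipeline."""


class TensiomapError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TensiomapError):
    """Invalid configuration or parameter value."""


class ConstantImageError(TensiomapError):
    """All intensities equal: no threshold separates two classes."""


class ChannelMissingError(TensiomapError):
    """A required named channel is absent from the image."""


class EmptyMaskError(TensiomapError):
    """A mask required to be non-empty has no positive pixel."""


class EmptyFibronectinMaskError(EmptyMaskError):
    """The fibronectin-positive mask (density denominator) is empty."""


class PlacementError(TensiomapError):
    """Object placement could not satisfy spacing within the retry budget."""


class EmptyGroupError(TensiomapError):
    """A grouping for summary statistics contains no usable record."""
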