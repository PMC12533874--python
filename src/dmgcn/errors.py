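"""Package-wide exception types."""


class DMGCNError(ValueError):
    """Base class for all errors raised by this package."""


class ConfigError(DMGCNError):
    """An invalid configuration value; the message names the offending field."""


class DataError(DMGCNError):
    """Inconsistent or unusable input data."""
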