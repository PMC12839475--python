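"""Exception hierarchy for tremorkit."""


class TremorKitError(Exception):
    """Base class for all tremorkit errors."""


class FormatError(TremorKitError):
    """A file does not conform to the expected on-disk format."""


class DataError(TremorKitError):
    """Input data violate a contract (non-monotone time, too few samples, ...)."""


class ConfigError(TremorKitError):
    """An analysis configuration is internally inconsistent or incompatible
    with the data (e.g. band edge at or above Nyquist)."""
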