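"""Exception hierarchy shared by all pipeline stages."""


class NegvolError(Exception):
    """Base class for all package errors."""


class FormatError(NegvolError):
    """Malformed or inconsistent input data (e.g. non-uniform DICOM pitch)."""


class GeometryError(NegvolError):
    """Invalid mesh or mask geometry (non-watertight, empty, degenerate)."""


class ConfigError(NegvolError):
    """Invalid configuration value or unknown configuration key."""


class PhantomSpecError(ConfigError):
    """Phantom geometry does not fit the requested grid."""


class ResourceError(NegvolError):
    """Requested computation exceeds the configured memory budget."""


class DivergenceError(NegvolError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class LocalizationError(NegvolError):
    """Joint localization did not produce one component per body side."""


class MetricError(NegvolError):
    """A metric is undefined for the given inputs (e.g. both masks empty)."""
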