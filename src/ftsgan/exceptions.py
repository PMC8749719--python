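"""Exception hierarchy shared across the package."""


class FTSGANError(Exception):
    """Base class for all package errors."""


class DecodeError(FTSGANError, ValueError):
    """A file could not be decoded as an image."""


class DimensionError(FTSGANError, ValueError):
    """An image has invalid or unexpected dimensions."""


class AlignmentError(FTSGANError, ValueError):
    """Two images that must be pixel-aligned have mismatched dimensions."""


class ConfigurationError(FTSGANError, ValueError):
    """An invalid parameter or configuration value was supplied."""


class GenerationError(FTSGANError, ValueError):
    """A synthetic face could not be rendered inside the image frame."""


class DomainError(FTSGANError, ValueError):
    """A numeric argument lies outside the mathematical domain of an operation."""


class TrainingError(FTSGANError, RuntimeError):
    """Adversarial training failed (e.g. a loss became non-finite)."""


class ReportError(FTSGANError, ValueError):
    """Recognition results cannot be combined into a report."""
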