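"""Exception types raised by the pipeline stages."""


class StretchCaError(Exception):
    """Base class for all package errors."""


class NormalizationError(StretchCaError, ValueError):
    """Trace cannot be normalized (e.g. all-zero signal)."""


class CorrectionError(StretchCaError, ValueError):
    """Dark/flat correction frames are unusable."""


class RegistrationError(StretchCaError, RuntimeError):
    """Drift registration failed on a frame."""


class TransformEstimationError(StretchCaError, RuntimeError):
    """Cross-phase transform estimation failed."""


class PlacementError(StretchCaError, RuntimeError):
    """Could not place non-overlapping cells in the synthetic field."""


class InsufficientDataError(StretchCaError, ValueError):
    """Too few observations for the requested statistical test."""


class IntegrityError(StretchCaError, ValueError):
    """Inputs that must describe the same cell/sample disagree."""


class ConfigurationError(StretchCaError, ValueError):
    """Invalid or incomplete experiment configuration."""
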