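"""Exception hierarchy shared across the package."""


class SynaptiqError(Exception):
    """Base class for all package errors."""


class ParameterError(SynaptiqError, ValueError):
    """A model or configuration parameter is out of its valid range."""


class PlacementError(SynaptiqError):
    """Bouton placement failed within the configured attempt budget."""


class GeometryError(SynaptiqError):
    """A volume or VOI does not fit the requested geometry."""


class DegenerateDataError(SynaptiqError):
    """Too few voxels/samples, or zero variance where variance is required."""


class ClassificationError(SynaptiqError):
    """A score required for classification is missing."""


class ConfigError(SynaptiqError):
    """Run configuration failed schema validation."""


class IncompatibleSweepsError(SynaptiqError):
    """Two sweep sets differ in sampling rate or stimulus timing."""


class DetectionError(SynaptiqError):
    """Event detection cannot proceed (e.g. degenerate noise estimate)."""


class FitError(SynaptiqError):
    """A curve fit failed to converge."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NormalizationError(SynaptiqError):
    """Train normalization impossible (first-stimulus charge at noise floor)."""


class EmptyResultError(SynaptiqError):
    """An operation removed every trial/event, leaving nothing to analyze."""
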