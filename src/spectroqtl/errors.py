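"""Exception hierarchy for the spectroqtl pipeline."""


class SpectroQTLError(Exception):
    """Base class for all spectroqtl errors."""


class InvalidDesignError(SpectroQTLError):
    """A simulation design parameter is out of its valid range."""


class UnknownLocusError(SpectroQTLError):
    """A planted QTL refers to a chromosome or position not in the panel."""


class MissingComponentError(SpectroQTLError):
    """An amplitude table lacks a component required by the spectral model."""


class SpectrumParseError(SpectroQTLError):
    """A spectrum file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class CoverageError(SpectroQTLError):
    """Spectral coverage is smaller than a required wavenumber window."""


class DegenerateReferenceError(SpectroQTLError):
    """The water-vapor reference has zero curvature norm in the fit window."""


class DegenerateNormalizationError(SpectroQTLError):
    """The normalization window is constant; min-max scaling is undefined."""


class UndefinedTraitError(SpectroQTLError):
    """A composite or ratio trait is not defined for the requested tissue."""


class UnknownTissueError(SpectroQTLError):
    """Tissue name not present in the band registry."""


class UndefinedRatioError(SpectroQTLError):
    """A ratio trait has a zero denominator; carries the sample id."""

    def __init__(self, message: str, sample_id: str | None = None):
        super().__init__(message)
        self.sample_id = sample_id


class InsufficientDataError(SpectroQTLError):
    """Too few informative strains to run a scan."""


class ValidationError(SpectroQTLError):
    """Pipeline configuration failed validation before any compute."""


class StageFailureError(SpectroQTLError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
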