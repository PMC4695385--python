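"""Exception hierarchy for screen scoring."""


class ScreenScoreError(Exception):
    """Base class for all package errors."""


class FormatError(ScreenScoreError):
    """A file does not conform to the canonical table schema."""


class ValidationError(ScreenScoreError):
    """A dataset violates a structural invariant that blocks analysis."""


class InsufficientDataError(ScreenScoreError):
    """Too few observations for the requested statistic."""


class UndefinedStatisticError(ScreenScoreError):
    """The statistic is undefined on this input (e.g. zero variance)."""


class NormalizationError(ScreenScoreError):
    """Percent-of-control normalization is impossible (e.g. zero control mean)."""


class CalibrationError(ScreenScoreError):
    """No growth cutoff achieves the requested control-set FDR.

    Carries the full FDR curve so the caller can inspect why.
    """

    def __init__(self, message, calibration=None):
        super().__init__(message)
        self.calibration = calibration


class FitError(ScreenScoreError):
    """Nonlinear fit failed to converge; carries the initialization used."""

    def __init__(self, message, init=None, trace=None):
        super().__init__(message)
        self.init = init
        self.trace = trace


class DomainError(ScreenScoreError):
    """An argument lies outside the mathematical domain of the operation."""


class PipelineStageError(ScreenScoreError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause
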