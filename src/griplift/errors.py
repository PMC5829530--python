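"""Exception hierarchy for the grip-lift pipeline.

Every failure mode the pipeline can signal is a subclass of
:class:`GripLiftError`, so callers can catch the whole family at once
(the session driver does exactly that to flag bad trials without
aborting a batch).  Subclasses additionally inherit from the closest
builtin (``ValueError``/``RuntimeError``) so code that never imports
this module still fails in an idiomatic way.
"""


class GripLiftError(Exception):
    """Base class for all griplift errors."""


class ConfigurationError(GripLiftError, ValueError):
    """Invalid simulation or analysis configuration; names the offending field."""


class FormatError(GripLiftError, ValueError):
    """Malformed trial file, sidecar or manifest."""


class NonFiniteSignalError(FormatError):
    """A signal contains NaN or infinite samples; no imputation is attempted."""


class ShortSignalError(GripLiftError, ValueError):
    """Signal too short for the requested operation (filtering, rates, fits)."""


class SegmentationError(GripLiftError, RuntimeError):
    """Base class for event-detection failures on a trial."""


class OnsetNotFoundError(SegmentationError):
    """No sustained supra-threshold force-rate run: absent or failed lift."""


class EndNotFoundError(SegmentationError):
    """No sustained release (load-force rate never below threshold)."""


class LiftFailureError(SegmentationError):
    """Load force never reaches object weight: the object was not lifted."""


class InconsistentTrialError(SegmentationError):
    """Detected events violate the required ordering tGFo <= tLFo < tLFw <= tEnd."""


class FitFailureError(GripLiftError, RuntimeError):
    """Nonlinear fit did not converge after bounded restarts.

    Carries ``best_rmse``, the smallest residual reached before giving up.
    """

    def __init__(self, message: str, best_rmse: float = float("nan")):
        super().__init__(message)
        self.best_rmse = best_rmse


class UndefinedCorrelationError(GripLiftError, RuntimeError):
    """Cross-correlation undefined (zero-variance segment)."""


class UndefinedGainError(GripLiftError, ZeroDivisionError):
    """Fixed-margin gain undefined for a zero gravity step."""


class InsufficientDataError(GripLiftError, ValueError):
    """Too few observations for the requested aggregate."""


class TrialAnalysisError(GripLiftError, RuntimeError):
    """Wrapper attaching a trial identifier to any stage failure."""
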