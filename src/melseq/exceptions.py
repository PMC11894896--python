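"""Exception hierarchy."""


class MelseqError(Exception):
    """Base class for package errors."""


class FitError(MelseqError):
    """Data unsuitable for fitting (e.g., no events)."""


class ConvergenceError(MelseqError):
    """Optimizer failed to converge; carries the best point found."""

    def __init__(self, message, best_result=None):
        super().__init__(message)
        self.best_result = best_result


class DataIntegrityError(MelseqError):
    """Inconsistent patient history (e.g., progression after death)."""


class ConfigError(MelseqError):
    """Invalid run configuration."""


class EngineError(MelseqError):
    """Cohort engine cannot proceed (e.g., missing transition fit)."""
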