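"""Exception hierarchy shared across the package."""


class StabmiError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StabmiError):
    """A variable specification or analysis config is inconsistent."""


class ParseError(StabmiError):
    """A CSV cell could not be interpreted under the declared spec."""


class DegenerateDataError(StabmiError):
    """The data cannot support the requested computation (e.g. one-class outcome)."""


class DegeneratePredictorError(StabmiError):
    """A predictor is constant or otherwise uninformative."""


class UndefinedChangeError(StabmiError):
    """Relative change is undefined because the baseline score is zero."""


class NonConvergenceError(StabmiError):
    """A maximum-likelihood fit failed to converge (e.g. complete separation).

    Carries the predictor set that was being fitted so bootstrap callers can
    flag the replicate instead of aborting the whole run.
    """

    def __init__(self, message, predictors=()):
        super().__init__(message)
        self.predictors = tuple(predictors)


class ValidationError(StabmiError):
    """Internal validation failed (too many failed bootstrap replicates)."""
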