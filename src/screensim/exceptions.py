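"""Exception hierarchy for screensim.

Errors are split into configuration problems (the caller asked for
something incoherent), validation problems (the data violate a contract),
and infeasibility (the data are valid but too small for the requested
simulation -- e.g. fewer than two relevant records).
"""


class ScreensimError(Exception):
    """Base class for all screensim errors."""


class ConfigurationError(ScreensimError):
    """A requested column, parameter or option is missing or out of range."""


class ValidationError(ScreensimError):
    """Input data violate a corpus contract (duplicate ids, bad label cell)."""


class EmptyCorpusError(ScreensimError):
    """Preprocessing removed every record."""


class FeaturizationError(ScreensimError):
    """No usable tokens: the vocabulary would be empty."""


class UndefinedKappaError(ScreensimError):
    """Cohen's kappa is undefined (chance agreement equals 1).

    Carries the 2x2 contingency so the caller can report the degenerate
    table instead of fabricating an agreement value.
    """

    def __init__(self, message, contingency=None):
        super().__init__(message)
        self.contingency = contingency


class InfeasibleSimulationError(ScreensimError):
    """The pool cannot support a simulation.

    A run needs at least one relevant record as training data and one
    relevant record as a target to detect, plus the ten irrelevant
    training records.
    """


class CalibrationError(ScreensimError):
    """The requested rater-agreement target is unattainable.

    Carries the attainable kappa interval for the given marginals.
    """

    def __init__(self, message, attainable_range=None):
        super().__init__(message)
        self.attainable_range = attainable_range


class StudyError(ScreensimError):
    """No stage of a study was feasible."""
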