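"""Exception hierarchy for the cost-of-illness toolkit."""


class HfcoiError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HfcoiError):
    """A configuration value is missing, malformed, or out of range."""


class DataValidationError(HfcoiError):
    """A patient record or input table violates a data invariant."""


class CalibrationError(HfcoiError):
    """Requested marginal moments are infeasible for the mixture family."""


class SpecValidationError(HfcoiError):
    """A Markov specification violates structural invariants.

    Carries the full list of violations, never just the first one.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "invalid Markov specification:\n  - " + "\n  - ".join(self.violations)
        )


class EstimationError(HfcoiError):
    """A regression part could not be estimated (separation, rank deficiency,
    non-convergence)."""


class PipelineError(HfcoiError):
    """A pipeline stage is missing an upstream artifact or failed to run."""
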