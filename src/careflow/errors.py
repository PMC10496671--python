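"""Exception hierarchy for careflow."""


class CareflowError(Exception):
    """Base class for all careflow errors."""


class BundleValidationError(CareflowError):
    """A parameter bundle violates one or more structural invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "parameter bundle failed validation:\n  - " + "\n  - ".join(self.violations)
        )


class BundleLoadError(CareflowError):
    """A bundle directory or one of its tables could not be parsed."""


class EstimationError(CareflowError):
    """Parameter estimation from an event log failed."""


class ClassificationError(EstimationError):
    """An ED row is missing the flags needed for avoidable classification."""


class FitError(EstimationError):
    """Distribution fitting could not proceed (e.g. too few samples)."""


class DegenerateDataError(FitError):
    """Samples carry no variance; no parametric family can be selected."""


class SamplingError(CareflowError):
    """A fitted distribution has an invalid parameter vector."""


class SimulationError(CareflowError):
    """The engine hit an unsimulable configuration (e.g. a missing delay)."""
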