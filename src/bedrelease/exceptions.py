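"""Exception hierarchy for bedrelease.

All package errors derive from :class:`BedReleaseError` so callers can catch
everything from one place; the subclasses mirror the distinct failure modes of
the pipeline stages.
"""


class BedReleaseError(Exception):
    """Base class for all bedrelease errors."""


class InvalidParameterError(BedReleaseError, ValueError):
    """A numeric parameter is outside its admissible range."""


class ValidationError(BedReleaseError, ValueError):
    """Input records violate the patient-record contract.

    ``messages`` carries one entry per offending record/row so that all
    problems in a file are reported together.
    """

    def __init__(self, messages):
        if isinstance(messages, str):
            messages = [messages]
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


class EstimandUndefinedError(BedReleaseError):
    """The change-in-LOS estimand has no support in the data.

    Raised when there are no observed transitions into the intermediate
    state, or when the weighting distribution over intervention times
    degenerates (no one ever at risk in the initial state afterwards).
    """


class InferenceFailureError(BedReleaseError):
    """Bootstrap produced too many undefined replicates to summarise."""


class CalibrationError(BedReleaseError):
    """A synthetic scenario cannot meet its configured summary tolerances."""


class EconEvaluationUndefinedError(BedReleaseError):
    """Cost per bed day is undefined (no simulation releases any bed days)."""


class InvalidStateError(BedReleaseError, ValueError):
    """An operation was asked for a state it is not defined on."""


class PipelineError(BedReleaseError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, original):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
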