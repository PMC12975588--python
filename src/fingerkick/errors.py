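"""Exception hierarchy for the finger-kick pipeline."""


class FingerkickError(Exception):
    """Base class for all package errors."""


class FormatError(FingerkickError):
    """A file does not conform to the declared dialect (missing column, unknown parameter...)."""


class DataError(FingerkickError):
    """The file parses but its content violates an invariant (non-monotone time, duplicates...)."""


class ValidationError(FingerkickError):
    """An in-memory value violates a domain constraint (out-of-range score, bad config...)."""


class NoMovementError(DataError):
    """No movement onset satisfying the velocity-threshold persistence rule was found."""

    def __init__(self, trial_id: str | None = None):
        self.trial_id = trial_id
        msg = "no movement detected"
        if trial_id is not None:
            msg += f" in trial {trial_id!r}"
        super().__init__(msg)


class FitError(FingerkickError):
    """Mixed-model estimation failed (singular information, non-convergence...)."""
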