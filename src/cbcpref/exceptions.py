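"""Exception and warning types shared across the package."""


class CBCError(Exception):
    """Base class for all cbcpref errors."""


class InvalidSchemaError(CBCError):
    """An attribute/level schema violates its invariants."""


class InfeasibleDesignError(CBCError):
    """The requested design cannot be constructed (e.g. more alternatives
    than distinct profiles)."""


class CorruptDesignError(CBCError):
    """A design references level indices outside the schema."""


class NoValidHoldoutError(CBCError):
    """Bounded search found no profile pair whose predicted share falls in
    the requested band."""


class TargetNotMetError(CBCError):
    """No sample size on the grid met the standard-error criterion.

    Carries the SE-vs-n table so callers can extend the grid.
    """

    def __init__(self, message, table=None):
        super().__init__(message)
        self.table = table


class AlignmentError(CBCError):
    """Inputs that must be paired (respondents/designs, predicted/observed
    shares, T1/T2 importances) do not line up."""


class ChoiceDataError(CBCError):
    """Long-format choice data failed validation; message names the rows."""


class ConfigurationError(CBCError):
    """Invalid simulation or pipeline configuration."""


class UndefinedImportanceError(CBCError):
    """Relative importance is undefined because every attribute's utility
    range is zero."""


class DegenerateTableError(CBCError):
    """Cohen's kappa is undefined (expected agreement equals 1)."""


class PipelineStageError(CBCError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage, message):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


class SeparationWarning(UserWarning):
    """Quasi-complete separation detected in a logit fit; estimates capped."""


class ConvergenceWarning(UserWarning):
    """An iterative fit stopped before meeting its tolerance, or an MCMC
    diagnostic exceeded its threshold."""
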