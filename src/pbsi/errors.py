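"""Exception hierarchy for the pbsi package."""


class PBSIError(Exception):
    """Base class for all package-specific errors."""


class SpecValidationError(PBSIError, ValueError):
    """A cohort specification field is invalid. The message names the field."""


class TableValidationError(PBSIError, ValueError):
    """A morphometry/clinical table violates its contract."""


class ProfileError(PBSIError, ValueError):
    """A regional profile is unusable (wrong length, missing, or constant)."""


class GroupTooSmallError(PBSIError, ValueError):
    """A diagnostic group has too few members for the requested statistic."""


class HarmonizationError(PBSIError, ValueError):
    """Batch-adjustment model cannot be fitted or applied."""


class AnalysisError(PBSIError, ValueError):
    """A statistical analysis precondition is violated."""
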