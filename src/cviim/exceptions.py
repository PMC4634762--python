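"""Exception hierarchy for the cviim package."""


class CviimError(Exception):
    """Base class for all package-specific errors."""


class PipelineCompositionError(CviimError):
    """An addon transform cannot be applied (e.g. variable-count mismatch).

    Raised with the offending step named so a mis-specified chain is easy
    to locate.
    """


class FitFailureError(CviimError):
    """A step or classifier could not be fitted on the given training data
    (singular covariance, degenerate scale, all-missing variable, ...)."""


class InfeasiblePartitionError(CviimError, ValueError):
    """A class-stratified K-fold partition is impossible (a class has fewer
    than K members)."""


class DegenerateFoldError(CviimError):
    """A training fold lost one of the two classes; fitting would be
    meaningless, so this is a hard error rather than a silent skip."""


class DataFormatError(CviimError, ValueError):
    """A dataset or config file could not be parsed into the expected shape."""
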