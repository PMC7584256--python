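"""Exception hierarchy.

All package errors derive from :class:`MltveError` so callers (and the CLI)
can catch everything from one base while tests discriminate by subclass.
"""


class MltveError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MltveError):
    """A user-supplied configuration is malformed or references unknown columns."""


class ValidationError(MltveError):
    """Input data violate a structural invariant (level-2 constancy, group counts...)."""


class DomainError(MltveError):
    """A transformation was evaluated outside its mathematical domain."""


class ConvergenceError(MltveError):
    """A model fit failed to converge or the fit is degenerate (e.g. separation)."""


class RankDeficiencyError(MltveError):
    """A design matrix is rank deficient; names the offending columns."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"design matrix is rank deficient; collinear columns: {self.columns}")


class InferenceError(MltveError):
    """Bootstrap or interval construction cannot proceed (too few replicates...)."""
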