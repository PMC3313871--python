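"""Exception hierarchy.

Two branches matter to callers: :class:`InputError` (bad inputs or
configuration; the CLI exits 1) and :class:`EstimationError` (the inputs were
well-formed but the requested statistic is undefined on them; the CLI exits 2).
"""


class IccWatchError(Exception):
    """Base class for all iccwatch errors."""


class InputError(IccWatchError):
    """Invalid input data, file, or configuration."""


class ValidationError(InputError):
    """A table or config violates its declared invariants."""


class VariableNotFoundError(InputError):
    """Requested variable has no rows in the table."""


class EstimationError(IccWatchError):
    """A statistic is undefined for the given (valid) data."""


class NoDataError(EstimationError):
    """No non-missing observations to work with."""


class InsufficientClustersError(EstimationError):
    """Fewer centers than the operation requires."""


class WithinVarianceUndefinedError(EstimationError):
    """All centers are singletons: N == k, so MSW has zero df."""


class DegenerateVarianceError(EstimationError):
    """Total variance is (numerically) zero; the ICC is undefined."""


class SnapshotRegressionError(InputError):
    """A supposedly cumulative snapshot lost rows relative to history."""


class CorrectionError(InputError):
    """A correction rule cannot be applied."""


class NoMatchingRowsError(CorrectionError):
    """The correction rule matches no rows in the table."""


class RuleAlreadyAppliedError(CorrectionError):
    """The correction rule was already applied to this table."""
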