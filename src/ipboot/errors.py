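"""Exception hierarchy shared across the package."""


class IPBError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(IPBError):
    """Malformed input data: missing columns, non-numeric cells, bad probabilities."""


class InvalidDesignError(IPBError):
    """A sampling design that cannot be realized on the given frame."""


class PartitionError(InvalidDesignError):
    """Design strata do not partition the population frame."""


class SingularFitError(IPBError):
    """An estimator could not be fit (rank-deficient or degenerate data)."""


class FailureBudgetExceeded(IPBError):
    """Too many per-iteration (or per-point) failures to trust the aggregate."""
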