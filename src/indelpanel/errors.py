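"""Exception hierarchy shared across the package."""


class IndelPanelError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(IndelPanelError, ValueError):
    """A file could not be parsed into a valid table."""


class ValidationError(IndelPanelError, ValueError):
    """An in-memory object violates a structural invariant."""


class EmptyDataError(IndelPanelError, ValueError):
    """An operation received no usable (non-missing) observations."""


class InconsistencyError(IndelPanelError, ValueError):
    """Printed summary values cannot arise from any integer genotype counts."""


class UndefinedStatisticError(IndelPanelError, ValueError):
    """The requested statistic is undefined for this input (e.g. a
    Hardy-Weinberg test or an LD coefficient at a monomorphic locus)."""
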