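"""Exception hierarchy shared across the package."""


class ZoocommError(Exception):
    """Base class for all package errors."""


class ValidationError(ZoocommError):
    """Raised when an input table or configuration violates its contract."""


class ClassificationError(ZoocommError):
    """Raised when a trait combination falls outside the functional-group map."""


class UndefinedStatisticError(ZoocommError):
    """Raised when a statistic is requested on degenerate input (e.g. all-zero scope)."""
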