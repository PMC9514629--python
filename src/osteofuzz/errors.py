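"""Exception hierarchy shared across the package."""


class OsteofuzzError(Exception):
    """Base class for all package errors."""


class InputError(OsteofuzzError):
    """A numeric input violates a precondition (non-finite, negative, ...)."""


class DomainError(OsteofuzzError):
    """A crisp value lies outside a linguistic variable's domain and
    clamping is disabled."""


class FuzzyConfigError(OsteofuzzError):
    """Inconsistent membership/rule/variable configuration."""


class DefuzzificationError(OsteofuzzError):
    """All output activations are zero; the rule base failed to cover the
    presented state."""


class SchemaError(OsteofuzzError):
    """A measurement table violates the CSV schema."""


class DesignError(OsteofuzzError):
    """An experimental design (study or factorial) is infeasible or
    inconsistent."""


class DataError(OsteofuzzError):
    """A measurement item cannot be resolved against the study designs."""


class ParameterError(OsteofuzzError):
    """A model parameter violates its bounds or ordering constraints."""
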