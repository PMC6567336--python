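"""Exception hierarchy shared across the package."""


class SeapenError(Exception):
    """Base class for all package errors."""


class SchemaError(SeapenError):
    """A table or configuration file is missing required structure."""


class ValidationError(SeapenError):
    """A value violates a domain invariant (names the offending rule)."""


class EmptyInputError(SeapenError):
    """An operation received an empty table or sample it cannot work on."""


class RankDeficiencyError(SeapenError):
    """A regression design matrix does not have full column rank."""


class InfeasibleMomentsError(SeapenError):
    """Requested moment targets violate the kurtosis > skewness^2 + 1 bound."""
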