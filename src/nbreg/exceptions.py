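"""Exception hierarchy for nbreg."""


class NBRegError(Exception):
    """Base class for all nbreg errors."""


class SchemaError(NBRegError):
    """A required column is missing or the column mapping is inconsistent."""


class ParseError(NBRegError):
    """A cell could not be parsed as the declared type (reports the row)."""


class ValidationError(NBRegError):
    """The data violate a dataset invariant (arm counts, tx coding, ...)."""


class SingularDesignError(NBRegError):
    """The design matrix is rank deficient; names the collinear columns."""


class InsufficientDataError(NBRegError):
    """Too few observations for the requested model (df_resid < 1)."""


class DomainError(NBRegError, ValueError):
    """An argument is outside its mathematical domain (e.g. negative WTP)."""
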