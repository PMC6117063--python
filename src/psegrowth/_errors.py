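"""Exception hierarchy shared by all pipeline stages."""


class PsegrowthError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PsegrowthError):
    """A file or mapping does not match the expected schema (missing or unknown keys)."""


class ValidationError(PsegrowthError):
    """A value violates a documented invariant (e.g. non-positive volume)."""


class MissingDataError(PsegrowthError):
    """An operation requires measurements that are absent from the record."""


class ConvergenceError(PsegrowthError):
    """A numerical solver failed to converge; carries diagnostics in the message."""
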