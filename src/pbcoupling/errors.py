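"""Exception hierarchy shared across the package."""


class PbcError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PbcError):
    """A data-model invariant was violated (names the field and article)."""


class ParseError(PbcError):
    """An input document could not be parsed."""


class SchemaError(PbcError):
    """A tabular input file does not match the documented column layout."""


class UnknownReferenceError(PbcError, KeyError):
    """A reference id was looked up in an article that does not contain it."""


class ConfigError(PbcError):
    """An infeasible or invalid configuration was supplied."""
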