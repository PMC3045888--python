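"""Exception types shared across the pipeline stages."""


class EstmineError(Exception):
    """Base class for all package errors."""


class ParameterError(EstmineError):
    """A function argument is out of its documented domain."""


class FormatError(EstmineError):
    """An input record violates its format contract (e.g. non-ACGTN bases)."""


class DataError(EstmineError):
    """Cross-references between records are inconsistent (e.g. unknown library)."""


class ConfigError(EstmineError):
    """A pipeline configuration fails schema validation."""
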