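"""Exception hierarchy for the qwa package."""


class QWAError(Exception):
    """Base class for all qwa errors."""


class SchemaError(QWAError):
    """A required column or field is missing from an input table."""


class ValidationError(QWAError):
    """An input value violates a schema invariant (e.g. non-positive
    dimension, duplicate key, month out of range)."""


class ParseError(QWAError):
    """A file could not be parsed (malformed line, bad sentinel, ...)."""


class ConfigurationError(QWAError):
    """Inconsistent or incomplete configuration / arguments."""


class AnalysisError(QWAError):
    """An analysis precondition failed (series too short, zero variance,
    insufficient overlap, empty ring, ...)."""
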