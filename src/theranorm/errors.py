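"""Exception hierarchy for theranorm."""


class TheranormError(Exception):
    """Base class for all theranorm errors."""


class ParseError(TheranormError):
    """A line of the record interchange stream could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class DuplicateRecordError(TheranormError):
    """Two records in one stream declared the same identifier."""


class SourceMismatchError(TheranormError):
    """A record's namespace does not match the declaring source."""


class UnknownNamespaceError(TheranormError):
    """A namespace is neither a registered source nor a registered external."""


class RecordValidationError(TheranormError):
    """One or more records violated schema invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "; ".join(str(v) for v in self.violations) or "invalid record"
        )


class ConfigError(TheranormError):
    """Invalid configuration (registry, fixture spec, vocabulary set)."""


class SchemaVersionError(TheranormError):
    """A persisted index snapshot has an unsupported schema version."""
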