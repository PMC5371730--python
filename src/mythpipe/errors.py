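"""Exception hierarchy shared across the pipeline."""


class MythpipeError(Exception):
    """Base class for all package errors."""


class SchemaError(MythpipeError):
    """A table is missing a mandatory column or has an unusable header."""


class RowError(MythpipeError):
    """A data row is malformed; carries the 1-based physical line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class DomainError(MythpipeError):
    """A numeric argument violates its mathematical domain."""


class ConfigurationError(MythpipeError):
    """A run/filter configuration is incomplete or inconsistent."""


class InconsistencyError(MythpipeError):
    """Inputs contradict each other (e.g. annotation vs background counts)."""
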