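"""Exception hierarchy shared across the pipeline."""


class ProxiprofError(Exception):
    """Base class for all package errors."""


class TableFormatError(ProxiprofError):
    """A table is structurally invalid (missing column, unknown token)."""


class RowParseError(TableFormatError):
    """A single row could not be parsed; carries the 0-based data row index."""

    def __init__(self, message: str, row_index: int):
        super().__init__(message)
        self.row_index = row_index


class ConfigurationError(ProxiprofError):
    """A run configuration or parameter set is inconsistent."""


class ParameterError(ConfigurationError):
    """Simulation parameters failed validation; carries offending field names."""

    def __init__(self, fields: list[str]):
        self.fields = list(fields)
        super().__init__(
            "invalid simulation parameters: " + ", ".join(self.fields)
        )
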