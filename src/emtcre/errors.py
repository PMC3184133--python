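"""Exception hierarchy shared across the pipeline stages."""


class ConfigurationError(ValueError):
    """Invalid configuration value or inconsistent parameter combination."""


class DataError(RuntimeError):
    """Input data violates a stage's contract (shape, labels, alphabet)."""


class ParseError(DataError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line
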