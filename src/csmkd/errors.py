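"""Exception hierarchy used across the package."""


class CsmkdError(Exception):
    """Base class for package errors."""


class ParameterError(CsmkdError, ValueError):
    """Invalid parameter value or combination."""


class InputError(CsmkdError, ValueError):
    """Inconsistent or malformed in-memory inputs (mismatched ids, mixed modes)."""


class GenerationError(CsmkdError, RuntimeError):
    """Synthetic-data generation could not satisfy its contract within retries."""


class ParseError(CsmkdError, ValueError):
    """Malformed file content; message names the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
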