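"""Exception types shared across the package."""


class AlarmcastError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AlarmcastError):
    """An invalid configuration value; the message names the offending field."""


class ParseError(AlarmcastError):
    """A malformed input file; carries the path and 1-based line number."""

    def __init__(self, message: str, path=None, line=None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
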