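"""Exception hierarchy.

``InputError`` marks a violated precondition on a call, ``DataError`` an
inconsistency inside otherwise well-formed data (e.g. a variant whose stated
reference base does not match the promoter sequence), and ``ConfigError`` an
invalid model or simulation configuration.
"""


class TatamarkError(Exception):
    """Base class for all package errors."""


class InputError(TatamarkError, ValueError):
    pass


class DataError(TatamarkError, ValueError):
    pass


class ConfigError(TatamarkError, ValueError):
    pass


class ParseError(TatamarkError, ValueError):
    """Malformed file content; carries a location when known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
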