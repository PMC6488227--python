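"""Exception hierarchy shared across the package."""


class MirspanError(Exception):
    """Base class for all errors raised by mirspan."""


class InputError(MirspanError):
    """An input file is unreadable or structurally malformed (wrong columns,
    unknown dialect, duplicate identifiers)."""


class ValidationError(MirspanError):
    """Inputs parse but violate a contract (zero kept edges, no mapped seeds,
    out-of-range probabilities). Carries optional diagnostic ``details``."""

    def __init__(self, message, details=None):
        super().__init__(message)
        self.details = details or {}
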