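"""Exception hierarchy for the beastsim pipeline."""


class BeastError(Exception):
    """Base class for all beastsim errors."""


class InvalidArgumentError(BeastError, ValueError):
    """An argument violates an operation's precondition."""


class NoValidSocialInfoError(BeastError, RuntimeError):
    """The candidate pool is empty after excluding values equal to E1."""


class UndefinedAdjustmentError(BeastError, ValueError):
    """The adjustment s = (E2-E1)/(X-E1) is undefined because X == E1."""


class InsufficientDataError(BeastError, ValueError):
    """Too few observations for the requested statistical procedure."""


class FormatError(BeastError, ValueError):
    """A file violates its schema. Carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
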