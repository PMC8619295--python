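"""Exception hierarchy shared across the curator modules."""


class CuratorError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CuratorError):
    """A tabular input is missing a required column or has a bad header."""


class ValidationError(CuratorError):
    """A record violates a catalog or hit-table invariant."""


class SequenceError(CuratorError):
    """A biological sequence is empty or contains an illegal character."""


class PatternError(CuratorError):
    """A PROSITE-syntax pattern failed to parse.

    Carries ``position``, the 0-based offset in the pattern string at
    which parsing failed.
    """

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position
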