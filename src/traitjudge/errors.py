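"""Exception types shared across the package."""


class TraitjudgeError(Exception):
    """Base class for package errors."""


class ValidationError(TraitjudgeError, ValueError):
    """Input violates a documented invariant (range, uniqueness, size)."""


class FormatError(TraitjudgeError, ValueError):
    """A file or table does not match the documented schema."""
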