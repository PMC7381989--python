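"""Exception types shared across glycoplan modules."""


class GlycoplanError(Exception):
    """Base class for all glycoplan errors."""


class DomainError(GlycoplanError, ValueError):
    """An input violates a documented precondition or invariant."""


class ValidationError(DomainError):
    """A document (meal DB, config, profile file) failed schema validation."""
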