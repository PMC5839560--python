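"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition (bad proportion, bounds, config...)."""


class UndefinedResultError(ArithmeticError):
    """The requested quantity is mathematically undefined for this input
    (e.g. a cost-effectiveness ratio at zero effectiveness, Cochran's Q
    with all-constant rows)."""
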