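"""Exception hierarchy shared across the package."""


class PrisError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PrisError, ValueError):
    """A value violates a domain invariant (range, membership, consistency)."""


class SchemaError(PrisError, ValueError):
    """A tabular input does not conform to the documented CSV schema."""


class DegenerateDesignError(PrisError, ValueError):
    """A statistical routine received an input it cannot fit (constant
    predictor, undefined baseline, missing cells)."""
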