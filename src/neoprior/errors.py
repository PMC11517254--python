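"""Exception hierarchy shared across the package."""


class NeopriorError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NeopriorError):
    """A file or table does not match the expected schema."""


class ValidationError(NeopriorError):
    """A value violates a documented invariant or precondition."""


class EmptyInputError(NeopriorError):
    """An operation received no usable input."""


class MissingScoreError(NeopriorError):
    """A predictor adapter could not resolve a queried key."""


class PoolTooSmallError(NeopriorError):
    """The TCR pool cannot supply the requested number of negatives."""


class StratificationError(NeopriorError):
    """A stratified split or CV fold cannot be formed."""


class DegenerateInputError(NeopriorError):
    """Input is structurally valid but the statistic is undefined on it."""
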