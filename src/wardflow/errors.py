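"""Exception hierarchy shared across wardflow modules."""


class WardflowError(Exception):
    """Base class for all wardflow errors."""


class ConfigurationError(WardflowError):
    """A configuration value violates its invariants (field headroom, k > Nn, ...)."""


class InputFormatError(WardflowError):
    """Malformed input data: duplicate records, off-grid timestamps, bad schema."""


class RangeError(WardflowError):
    """A secret lies outside the embeddable signed range [-M, M]."""


class InvariantViolationError(WardflowError):
    """An internal data invariant was violated (overlapping periods, bad row sums)."""


class PreprocessingExhaustedError(WardflowError):
    """The dealer tape ran out of precomputed triples or masks."""


class BudgetError(ConfigurationError):
    """Worst-case circuit bit growth exceeds the field's comparison headroom."""
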