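"""Shared exception types."""


class UndefinedValueError(ValueError):
    """A statistic is undefined on this input (e.g. no comparable alignment
    columns, or an empty denominator)."""
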