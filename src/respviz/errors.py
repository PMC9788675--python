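"""Package-wide exception types."""


class ValidationError(ValueError):
    """Raised when an input violates a documented contract.

    The message always names the offending field or input so callers can
    surface actionable errors from batch pipelines.
    """
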