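"""Shared constants and errors."""

CASE = "case"
CONTROL = "control"
GROUP_LABELS = (CASE, CONTROL)


class ValidationError(ValueError):
    """Raised when an input table or configuration violates its contract."""
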