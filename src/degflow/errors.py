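"""Error type shared across the pipeline."""

from __future__ import annotations


class DegflowError(ValueError):
    """Validation or processing failure with a stable machine-readable code.

    ``code`` is a short kebab-case label (e.g. ``"design-mismatch"``) that
    callers and tests can match on without parsing the human-readable message.
    """

    def __init__(self, code: str, message: str | None = None):
        self.code = code
        super().__init__(f"{code}: {message}" if message else code)
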