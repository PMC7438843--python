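"""Exception types shared across the pipeline.

``ValidationError`` marks bad inputs or configuration (CLI exit code 2);
anything else that escapes a stage is a runtime failure (exit code 3).
"""


class ValidationError(ValueError):
    """Raised when inputs, configuration, or file contents violate a contract."""
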