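"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input value violates a documented precondition."""


class FormatError(ValueError):
    """A file does not conform to its expected on-disk format."""
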