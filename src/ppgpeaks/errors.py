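"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A precondition on data or parameters was violated."""


class ParseError(ValueError):
    """A text record or annotation file could not be parsed."""
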