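"""Error types shared by the format readers/writers."""


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class DispatchError(ValueError):
    """No reader is registered for a path's extension."""
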