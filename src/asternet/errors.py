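"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A parameter block violates its own invariants."""


class DegenerateInputError(ValueError):
    """Input geometry cannot support the requested operation
    (fewer than three points, all collinear, zero image area, ...)."""


class ImageFormatError(ValueError):
    """An input image file is unreadable or not a single-channel 2D frame."""
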