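"""Exception types shared across the pipeline."""


class ParameterError(ValueError):
    """An argument or configuration value is out of its valid range."""


class SegmentationError(RuntimeError):
    """The pipeline could not produce a lumen object from this input."""
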