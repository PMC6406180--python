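"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """An invalid or internally inconsistent configuration was supplied."""


class EmptySelectionError(ValueError):
    """A filtering step selected no items (e.g. no gene passed the SD cut)."""
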