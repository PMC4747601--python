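"""Exception types shared across the package."""


class ConfigError(ValueError):
    """An invalid parameter or configuration value."""


class EmptyReadError(ValueError):
    """A zero-length read where a non-empty sequence is required."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""
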