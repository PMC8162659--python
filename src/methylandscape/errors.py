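"""Shared exception types."""


class ConfigError(ValueError):
    """Invalid or inconsistent configuration."""


class QCError(RuntimeError):
    """A quality-control precondition failed (e.g. no spike-in coverage)."""


class NumericalError(RuntimeError):
    """A numerical routine produced a non-finite or inconsistent result."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""
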