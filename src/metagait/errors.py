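"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid configuration (bad ranges, incompatible architecture settings)."""


class DomainError(ValueError):
    """Invalid argument for an operation (wrong modality, empty input, ...)."""


class TrainingError(RuntimeError):
    """Non-finite loss or other failure during optimization."""
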