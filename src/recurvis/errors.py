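"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A parameter or spec value is outside its legal range."""


class InvalidInputError(ValueError):
    """Input data (image, occlusion level, ...) violates a precondition."""


class SimulationError(RuntimeError):
    """Network state became non-finite or training diverged."""
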