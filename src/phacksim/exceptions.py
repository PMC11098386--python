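"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A parameter is outside its valid domain."""


class InvalidInputError(ValueError):
    """Structurally invalid input (length mismatch, empty collection, ...)."""


class SimulationError(RuntimeError):
    """The simulation reached an unrecoverable state (e.g. no survivors)."""
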