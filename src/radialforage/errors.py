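"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """Malformed or out-of-contract input (non-finite coordinates,
    nonpositive legs, bad rates, empty collections, ...)."""


class RadialLevelError(InvalidInputError):
    """Radial level k exceeds the size of the (possibly depleted) food set."""


class ConfigurationError(InvalidInputError):
    """Inconsistent run configuration (step count, level range, ...)."""
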