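"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """An input value violates a precondition (non-positive size, bad arity,
    missing required series, duplicate timepoints, unknown tokens...)."""


class ConfigurationError(ValueError):
    """A policy configuration is internally inconsistent or cannot serve a
    request (unknown policy label, empty threshold table...)."""


class CalibrationError(RuntimeError):
    """Threshold calibration has no root under the given error model."""
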