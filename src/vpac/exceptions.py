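"""Exception hierarchy for vpac."""


class VPACError(Exception):
    """Base class for all vpac errors."""


class ConfigurationError(VPACError, ValueError):
    """Invalid model configuration (e.g. latent dimension >= gene count)."""


class ValidationError(VPACError, ValueError):
    """Invalid input data (negative entries, mismatched identifiers, ...)."""


class FormatError(VPACError, ValueError):
    """A file could not be parsed under its declared format."""


class NumericalError(VPACError, FloatingPointError):
    """A numerical failure during inference (non-SPD matrix, underflow, ...)."""
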