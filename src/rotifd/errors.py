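"""Exception hierarchy used across the package."""


class RotifdError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RotifdError):
    """Invalid configuration value (unknown parameter, empty vocabulary, ...)."""


class ValidationError(RotifdError):
    """Input tables violate a structural contract (labels, indices, symmetry)."""


class DomainError(RotifdError, ValueError):
    """A numeric input falls outside the mathematical domain of an operation."""


class DegenerateError(RotifdError):
    """The computation is well-posed but degenerates (all-zero weights, empty space)."""
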