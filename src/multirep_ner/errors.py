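"""Exception hierarchy shared across the package."""


class MultirepError(Exception):
    """Base class for all package-specific errors."""


class InputError(MultirepError):
    """A required input (path, resource) is missing or unusable."""


class FormatError(MultirepError):
    """An input file exists but its content violates the expected format."""


class ConfigurationError(MultirepError):
    """A configuration value is invalid or inconsistent."""


class AlignmentError(MultirepError):
    """Candidate-id manifests of two aligned objects do not match."""


class ContractError(MultirepError):
    """A documented precondition was violated by the caller."""


class NumericError(MultirepError):
    """An iterative numeric procedure failed to converge or diverged."""
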