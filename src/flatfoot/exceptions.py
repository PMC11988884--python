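"""Exception hierarchy shared across the package."""


class FlatfootError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(FlatfootError, ValueError):
    """A configuration value violates its documented constraints."""


class InvalidInputError(FlatfootError, ValueError):
    """A runtime input (array, label sequence, ...) is malformed."""


class InvalidWeightsError(FlatfootError, ValueError):
    """Weight arrays are inconsistent with the configuration."""


class InvalidDatasetError(FlatfootError, ValueError):
    """An on-disk dataset does not follow the expected layout."""


class NumericError(FlatfootError, ArithmeticError):
    """Non-finite values were encountered where finite ones are required."""


class ChecksumError(FlatfootError):
    """A stored archive failed its integrity check."""


class UnsupportedVersionError(FlatfootError):
    """A stored archive was written by an incompatible format version."""
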