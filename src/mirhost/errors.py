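"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` subclasses to 3 and
anything else to 4.
"""


class MirhostError(Exception):
    """Base class for all package errors."""


class ConfigError(MirhostError):
    """Invalid run or simulation configuration."""


class DataError(MirhostError):
    """Problem with input data."""


class ExpressionParseError(DataError):
    """Malformed expression table."""


class AnnotationParseError(DataError):
    """Malformed miRNA-host or miRNA-target table."""


class EmptyDatasetError(DataError):
    """All genes were removed or no usable rows remain."""


class MissingGeneError(DataError, KeyError):
    """Requested gene absent from a dataset."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class DegenerateProfileError(DataError):
    """A profile that cannot be normalized (zero norm)."""


class NoRegulatorError(DataError):
    """Target has no putative miRNA regulator with a known host."""


class PermutationError(DataError):
    """Host-label permutation impossible (single-host universe)."""
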