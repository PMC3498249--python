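"""Exception hierarchy shared across the package.

All data/validation problems raise a subclass of :class:`ForestrecError`
so the CLI can map them to exit code 1 while genuine usage errors keep
exit code 2.
"""


class ForestrecError(Exception):
    """Base class for all forestrec-specific errors."""


class FormatError(ForestrecError):
    """An input table is structurally malformed (e.g. missing columns)."""


class ValidationError(ForestrecError):
    """A value violates a data-model invariant (negative counts, duplicates...)."""


class ReferentialError(ValidationError):
    """A census references a plot that has no metadata record."""


class CensusLookupError(ForestrecError):
    """A requested (plot, census) combination does not exist."""


class UndefinedSimilarityError(ForestrecError):
    """Similarity is undefined for the given inputs (e.g. two empty plots)."""


class DesignError(ForestrecError):
    """The plot/pair structure cannot support the requested analysis."""


class UndefinedRecoveryError(ForestrecError):
    """Percent-of-maximum is undefined because the maximum is not positive."""


class InsufficientDataError(ForestrecError):
    """Too few complete pairs (or observations) for the requested test."""


class ConfigError(ForestrecError):
    """A required configuration item is missing or inconsistent."""
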