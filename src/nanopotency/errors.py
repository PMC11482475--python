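"""Exception hierarchy for nanopotency.

All package-raised errors derive from :class:`NanopotencyError` so callers can
catch the whole family with one clause while still distinguishing validation
problems from design/degeneracy problems.
"""


class NanopotencyError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(NanopotencyError):
    """Inputs fail a precondition (non-finite values, out-of-range parameters)."""


class KeyingError(NanopotencyError):
    """Records that must share grouping keys (particle, cell type, ...) do not."""


class NormalizationError(NanopotencyError):
    """A group lacks the zero-dose control wells required for normalization."""


class DegenerateControlError(NanopotencyError):
    """Control signals exist but are unusable (non-positive mean)."""


class DegenerateInputError(NanopotencyError):
    """A statistic is undefined for the input (e.g. zero-variance vector)."""


class InsufficientDesignError(NanopotencyError):
    """The experimental design cannot identify the requested quantity."""


class DesignError(NanopotencyError):
    """The layout of groups/factors violates the analysis requirements."""


class CollinearityError(NanopotencyError):
    """The regression design matrix is rank deficient."""

    def __init__(self, message, aliased=()):
        super().__init__(message)
        self.aliased = tuple(aliased)


class DegenerateRowError(NanopotencyError):
    """A matrix row is constant where a correlation distance is required."""
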