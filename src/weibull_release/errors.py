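"""Exception hierarchy for the package.

All domain-level failures derive from :class:`ReleaseModelError` so callers
can distinguish bad inputs from genuine bugs.
"""


class ReleaseModelError(Exception):
    """Base class for all package errors."""


class DomainError(ReleaseModelError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DensityDivergesError(DomainError):
    """The release-speed density is unbounded at the requested time.

    Raised when the Weibull PDF is evaluated at t = 0 with shape ``beta < 1``,
    where the density has an integrable singularity.  Returning ``inf`` would
    let tabulation code silently propagate a non-physical number; failing
    loudly is the documented behaviour.
    """


class UnreachableReleaseError(DomainError):
    """A release target at or above the saturation plateau was requested."""


class FitError(ReleaseModelError):
    """A regression or nonlinear fit could not be carried out."""


class ProfileParseError(ReleaseModelError, ValueError):
    """A profile CSV file is malformed."""
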