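"""Transport-mechanism classification from fitted shape exponents.

Two diagnostics are supported: the Weibull shape factor ``beta`` and the
early-release power-law exponent ``n``.  Band edges are configurable; the
defaults encode the conventional reading of each exponent:

``beta``:
    beta <= 0.75          -> Fickian diffusion (fractal or Euclidean media)
    0.75 < beta < 1       -> combined Fickian diffusion + swelling transport
    beta == 1             -> first-order (exponential) release
    beta > 1              -> complex sigmoidal release with an inflection

``n`` (power-law slope):
    n <= 0.6              -> diffusion-controlled early release
    0.6 < n <= 1.2        -> zero-order-like (near-constant rate)
    n > 1.2               -> complex collective processes (swelling,
                             matrix degradation, ...)

Additionally, a fitted ``beta`` within ``first_order_tol`` of 1 carries a
"first-order-like" note, since such fits are statistically consistent with
simple exponential kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError

__all__ = ["MechanismLabel", "CATEGORIES", "classify_beta", "classify_powerlaw_slope"]

CATEGORIES = (
    "fickian_diffusion",
    "combined_fickian_swelling",
    "complex_sigmoidal",
    "first_order_like",
    "zero_order_like",
    "diffusion_controlled",
    "complex_collective",
)


@dataclass(frozen=True)
class MechanismLabel:
    """Categorical transport-mechanism call for one exponent value."""

    category: str  # one of CATEGORIES
    basis: str  # "beta" | "powerlaw_n"
    value: float
    note: str = ""


def classify_beta(
    beta: float, fickian_max: float = 0.75, first_order_tol: float = 0.1
) -> MechanismLabel:
    """Classify a Weibull shape factor into a release-mechanism category.

    ``beta == 1`` exactly is labelled ``first_order_like`` (the stretched
    exponential degenerates to a plain exponential there); any ``beta``
    within ``first_order_tol`` of 1 gets a first-order-like annotation in
    the note while keeping its band category.
    """
    if not beta > 0:
        raise DomainError(f"beta must be > 0, got {beta}")
    if beta == 1.0:
        category = "first_order_like"
        note = "beta = 1: exponential (first-order) release"
    elif beta <= fickian_max:
        category = "fickian_diffusion"
        note = f"beta <= {fickian_max}: Fickian diffusion (fractal or Euclidean)"
    elif beta < 1.0:
        category = "combined_fickian_swelling"
        note = (
            f"{fickian_max} < beta < 1: combined Fickian diffusion and "
            "swelling-controlled transport"
        )
    else:
        category = "complex_sigmoidal"
        note = (
            "beta > 1: sigmoidal release, rate rises to an inflection then "
            "decays"
        )
    if abs(beta - 1.0) <= first_order_tol and category != "first_order_like":
        note += "; first-order-like (beta within "
        note += f"{first_order_tol:g} of 1)"
    return MechanismLabel(category=category, basis="beta", value=float(beta), note=note)


def classify_powerlaw_slope(
    n: float, diffusion_max: float = 0.6, zero_order_max: float = 1.2
) -> MechanismLabel:
    """Classify an early-release power-law exponent ``n``.

    Band edges default to ``diffusion_max = 0.6`` and ``zero_order_max =
    1.2``; a slope near 0.5 is the classic square-root-of-time diffusion
    signature, slopes near 1 indicate near-constant-rate (zero-order)
    release, and larger slopes point at collective processes in the matrix.
    """
    if not n > 0:
        raise DomainError(f"power-law exponent must be > 0, got {n}")
    if not 0 < diffusion_max < zero_order_max:
        raise DomainError("require 0 < diffusion_max < zero_order_max")
    if n <= diffusion_max:
        category = "diffusion_controlled"
        note = f"n <= {diffusion_max:g}: diffusion-controlled early release"
    elif n <= zero_order_max:
        category = "zero_order_like"
        note = f"{diffusion_max:g} < n <= {zero_order_max:g}: near-constant release rate"
    else:
        category = "complex_collective"
        note = (
            f"n > {zero_order_max:g}: several collective processes "
            "(swelling, degradation) likely involved"
        )
    return MechanismLabel(category=category, basis="powerlaw_n", value=float(n), note=note)
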