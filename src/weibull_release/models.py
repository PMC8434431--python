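"""Closed-form release-model functions and derived time statistics.

The central object is the (non-normalized) Weibull cumulative release curve

    M(t) = m_inf * (1 - exp(-(t / tau_k)**beta))

with ``m_inf`` the saturation release in percent of loaded drug, ``tau_k``
the characteristic time in hours and ``beta`` the dimensionless shape
(stretching) exponent.  Its survival complement ``exp(-(t/tau_k)**beta)`` is
the classical stretched-exponential (Kohlrausch) relaxation function.

Units are fixed package-wide: time in **hours**, release in **percent** of
loaded drug.  All functions accept scalars or array-likes and broadcast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy.special import gamma as _gamma

from .errors import DensityDivergesError, DomainError, UnreachableReleaseError

__all__ = [
    "WeibullParams",
    "DerivedStats",
    "MechModelCoeffs",
    "MODEL_IDS",
    "weibull_cdf",
    "weibull_pdf",
    "weibull_inverse",
    "powerlaw_limit",
    "kohlrausch",
    "mean_release_time",
    "std_release_time",
    "mode_release_time",
    "derived_stats",
    "model_value",
]

ArrayLike = Union[float, Sequence[float], np.ndarray]


@dataclass(frozen=True)
class WeibullParams:
    """Parameters of the Weibull release model.

    Attributes
    ----------
    m_inf : float
        Maximum (saturation) released drug amount, percent of loaded drug.
    tau_k : float
        Characteristic release time, hours.  63.2% of ``m_inf`` is released
        at ``t = tau_k``.
    beta : float
        Dimensionless shape factor.
    """

    m_inf: float
    tau_k: float
    beta: float

    def __post_init__(self) -> None:
        if not self.m_inf >= 0:
            raise DomainError(f"m_inf must be >= 0, got {self.m_inf}")
        if not self.tau_k > 0:
            raise DomainError(f"tau_k must be > 0, got {self.tau_k}")
        if not self.beta > 0:
            raise DomainError(f"beta must be > 0, got {self.beta}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.m_inf, self.tau_k, self.beta)


@dataclass(frozen=True)
class DerivedStats:
    """Time statistics of the Weibull release model.

    ``mode_time`` is ``None`` for ``beta <= 1``, where the release-speed
    density is monotonically decreasing and has no interior maximum.
    """

    mean_time: float  # hours
    std_time: float  # hours
    mode_time: float | None  # hours, defined only for beta > 1


MODEL_IDS = ("zero_order", "first_order", "higuchi", "power_law", "weibull")

# model_id -> required number of coefficients
_N_COEFFS = {
    "zero_order": 1,  # (k0,) in %/h
    "first_order": 2,  # (k, m_inf): k in 1/h, plateau in %
    "higuchi": 1,  # (k_H,) in %/sqrt(h)
    "power_law": 2,  # (k, n): prefactor in %/h^n, exponent dimensionless
    "weibull": 3,  # (m_inf, tau_k, beta)
}


@dataclass(frozen=True)
class MechModelCoeffs:
    """Coefficients of one of the candidate mechanistic release models.

    Coefficient layout per ``model_id``:

    - ``zero_order``:  ``(k0,)``          — rate constant, %/h
    - ``first_order``: ``(k, m_inf)``     — rate 1/h, plateau %
    - ``higuchi``:     ``(k_H,)``         — constant, %/sqrt(h)
    - ``power_law``:   ``(k, n)``         — prefactor %/h^n, exponent
    - ``weibull``:     ``(m_inf, tau_k, beta)``
    """

    model_id: str
    coefficients: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise DomainError(
                f"unknown model_id {self.model_id!r}; expected one of {MODEL_IDS}"
            )
        coeffs = tuple(float(c) for c in self.coefficients)
        object.__setattr__(self, "coefficients", coeffs)
        want = _N_COEFFS[self.model_id]
        if len(coeffs) != want:
            raise DomainError(
                f"model {self.model_id!r} needs {want} coefficients, got {len(coeffs)}"
            )
        # rate constants / scale parameters must be positive
        if self.model_id in ("zero_order", "higuchi", "first_order", "power_law"):
            if coeffs[0] <= 0:
                raise DomainError(f"rate constant must be > 0, got {coeffs[0]}")


def _check_times(t: ArrayLike) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise DomainError("time must be >= 0")
    return arr


def weibull_cdf(t: ArrayLike, p: WeibullParams) -> np.ndarray | float:
    """Cumulative release M(t) = m_inf * (1 - exp(-(t/tau_k)**beta)), percent.

    Monotone non-decreasing in ``t`` and bounded by ``p.m_inf``.
    """
    arr = _check_times(t)
    out = p.m_inf * (-np.expm1(-((arr / p.tau_k) ** p.beta)))
    return out if isinstance(t, (np.ndarray, list, tuple)) else float(out)


def weibull_pdf(t: ArrayLike, p: WeibullParams) -> np.ndarray | float:
    """Release speed dM/dt, percent per hour.

    Raises
    ------
    DensityDivergesError
        If ``t`` contains 0 while ``beta < 1`` (density unbounded at zero).
    """
    arr = _check_times(t)
    if p.beta < 1 and np.any(arr == 0):
        raise DensityDivergesError(
            f"release speed diverges at t=0 for beta={p.beta} < 1"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        x = arr / p.tau_k
        out = (p.m_inf * p.beta / p.tau_k) * x ** (p.beta - 1) * np.exp(-(x**p.beta))
    # beta > 1: x**(beta-1) -> 0 at t=0; beta == 1: x**0 == 1 (numpy gives 1 at 0)
    out = np.where(arr == 0, p.m_inf / p.tau_k if p.beta == 1 else 0.0, out)
    return out if isinstance(t, (np.ndarray, list, tuple)) else float(out)


def weibull_inverse(m: ArrayLike, p: WeibullParams) -> np.ndarray | float:
    """Time (hours) at which cumulative release first reaches ``m`` percent.

    Closed-form inversion: ``tau_k * (-ln(1 - m/m_inf))**(1/beta)``.

    Raises
    ------
    UnreachableReleaseError
        If ``m >= m_inf`` (the plateau is never exceeded).
    DomainError
        If ``m < 0``.
    """
    arr = np.asarray(m, dtype=float)
    if np.any(arr < 0):
        raise DomainError("release target must be >= 0")
    if np.any(arr >= p.m_inf):
        raise UnreachableReleaseError(
            f"release target unreachable: saturation plateau is m_inf={p.m_inf}%"
        )
    out = p.tau_k * (-np.log1p(-arr / p.m_inf)) ** (1.0 / p.beta)
    return out if isinstance(m, (np.ndarray, list, tuple)) else float(out)


def powerlaw_limit(t: ArrayLike, p: WeibullParams) -> np.ndarray | float:
    """Small-argument power-law limit m_inf * (t/tau_k)**beta, percent.

    First-order expansion of :func:`weibull_cdf`, accurate while
    ``(t/tau_k)**beta`` is small; reduces to the square-root (Higuchi) law
    for ``beta = 1/2``.
    """
    arr = _check_times(t)
    out = p.m_inf * (arr / p.tau_k) ** p.beta
    return out if isinstance(t, (np.ndarray, list, tuple)) else float(out)


def kohlrausch(t: ArrayLike, tau_k: float, beta: float) -> np.ndarray | float:
    """Stretched-exponential survival fraction exp(-(t/tau_k)**beta).

    Equals ``1 - weibull_cdf(t, p)/m_inf``; dimensionless, in (0, 1].
    """
    if not tau_k > 0:
        raise DomainError(f"tau_k must be > 0, got {tau_k}")
    if not beta > 0:
        raise DomainError(f"beta must be > 0, got {beta}")
    arr = _check_times(t)
    out = np.exp(-((arr / tau_k) ** beta))
    return out if isinstance(t, (np.ndarray, list, tuple)) else float(out)


def mean_release_time(p: WeibullParams) -> float:
    """Mean release (relaxation) time (tau_k/beta) * Gamma(1/beta), hours.

    The equivalent form ``tau_k * Gamma(1 + 1/beta)`` is evaluated as well
    and asserted equal to 1e-12 relative, guarding against Gamma-argument
    mistakes.
    """
    a = (p.tau_k / p.beta) * _gamma(1.0 / p.beta)
    b = p.tau_k * _gamma(1.0 + 1.0 / p.beta)
    if not math.isclose(a, b, rel_tol=1e-12):
        raise AssertionError(f"gamma identity violated: {a!r} != {b!r}")
    return a


def std_release_time(p: WeibullParams) -> float:
    """Standard deviation of the release time, hours.

    sqrt( (tau_k**2/beta) * [2*Gamma(2/beta) - (1/beta)*Gamma(1/beta)**2] ),
    identically ``tau_k * sqrt(Gamma(1+2/beta) - Gamma(1+1/beta)**2)``.
    """
    b = p.beta
    var = (p.tau_k**2 / b) * (2.0 * _gamma(2.0 / b) - (1.0 / b) * _gamma(1.0 / b) ** 2)
    var = max(var, 0.0)  # guard tiny negative round-off
    return math.sqrt(var)


def mode_release_time(p: WeibullParams) -> float | None:
    """Time of maximum release speed, hours; ``None`` unless ``beta > 1``."""
    if p.beta <= 1:
        return None
    return p.tau_k * ((p.beta - 1.0) / p.beta) ** (1.0 / p.beta)


def derived_stats(p: WeibullParams) -> DerivedStats:
    """Bundle mean, standard deviation and mode of the release time."""
    return DerivedStats(
        mean_time=mean_release_time(p),
        std_time=std_release_time(p),
        mode_time=mode_release_time(p),
    )


def model_value(c: MechModelCoeffs, t: ArrayLike) -> np.ndarray | float:
    """Evaluate a candidate mechanistic model at time ``t`` (percent).

    - ``zero_order``:  k0 * t
    - ``first_order``: m_inf * (1 - exp(-k t))
    - ``higuchi``:     k_H * sqrt(t)
    - ``power_law``:   k * t**n
    - ``weibull``:     delegates to :func:`weibull_cdf`
    """
    arr = _check_times(t)
    co = c.coefficients
    if c.model_id == "zero_order":
        out = co[0] * arr
    elif c.model_id == "first_order":
        out = co[1] * (-np.expm1(-co[0] * arr))
    elif c.model_id == "higuchi":
        out = co[0] * np.sqrt(arr)
    elif c.model_id == "power_law":
        out = co[0] * arr ** co[1]
    else:  # weibull; model_id already validated in MechModelCoeffs
        return weibull_cdf(t, WeibullParams(*co))
    return out if isinstance(t, (np.ndarray, list, tuple)) else float(out)
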