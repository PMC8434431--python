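"""Parameter estimation from cumulative release profiles.

Three complementary routes are provided:

1. log-log power-law regression of the early release (exponent ``n``),
2. the Weibull-plot linearization
   ``ln(-ln(1 - M/m_inf))`` vs ``ln t`` (slope = ``beta``), used both as a
   diagnostic and as the initializer for
3. nonlinear least squares on the Weibull CDF itself,

plus goodness-of-fit metrics and comparison against the classical
mechanistic candidates (zero-order, first-order, Higuchi, power law).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import DomainError, FitError
from .models import (
    MODEL_IDS,
    MechModelCoeffs,
    WeibullParams,
    model_value,
    weibull_cdf,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReleaseProfile",
    "LinearFit",
    "WeibullPlotFit",
    "WeibullFit",
    "ModelFitRecord",
    "ModelComparison",
    "loglog_powerlaw_fit",
    "default_powerlaw_window",
    "weibull_plot_transform",
    "weibull_plot_fit",
    "fit_weibull_cdf",
    "goodness_of_fit",
    "compare_models",
]

# nonlinear-fit convergence policy (documented contract)
_XTOL = 1e-8
_MAX_NFEV = 500


@dataclass(frozen=True)
class ReleaseProfile:
    """A measured or simulated cumulative release time series.

    ``times`` in hours, ``release`` in percent of loaded drug.  Points are
    sorted by time at construction; duplicate times are rejected.
    """

    times: np.ndarray
    release: np.ndarray
    label: str = ""
    m_inf_hint: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.release, dtype=float)
        if t.ndim != 1 or r.ndim != 1 or t.size != r.size:
            raise DomainError("times and release must be 1-D and equal length")
        if t.size < 3:
            raise DomainError(f"need at least 3 points, got {t.size}")
        order = np.argsort(t, kind="stable")
        t, r = t[order], r[order]
        if np.any(t < 0):
            raise DomainError("times must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise DomainError("times must be distinct (duplicates found)")
        if np.any(r < 0):
            raise DomainError("release values must be >= 0")
        if self.m_inf_hint is not None and not self.m_inf_hint > 0:
            raise DomainError("m_inf_hint must be > 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "release", r)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def plateau(self) -> float:
        """Saturation estimate: the hint if given, else the maximum release."""
        return self.m_inf_hint if self.m_inf_hint is not None else float(
            np.max(self.release)
        )


@dataclass(frozen=True)
class LinearFit:
    """Slope/intercept/R^2 summary of a linearization diagnostic."""

    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    n_points: int
    window: tuple[float, float]  # (t_min, t_max), hours


@dataclass(frozen=True)
class WeibullPlotFit(LinearFit):
    """Weibull-plot linearization; exposes starting values for the CDF fit.

    ``beta0 = slope`` and ``tau_k0 = exp(-intercept/slope)``.
    """

    beta0: float = float("nan")
    tau_k0: float = float("nan")
    n_excluded: int = 0


@dataclass(frozen=True)
class WeibullFit:
    """Result of the nonlinear Weibull CDF fit."""

    params: WeibullParams
    param_ses: Mapping[str, float]  # keys: tau_k, beta, and m_inf when free
    m_inf_fixed: bool
    residual_rmse: float
    r_squared: float
    aicc: float
    converged: bool
    n_evaluations: int
    message: str = ""


@dataclass(frozen=True)
class ModelFitRecord:
    """One candidate model's fitted coefficients and fit quality."""

    coeffs: MechModelCoeffs
    r_squared: float
    rmse: float
    aicc: float


@dataclass(frozen=True)
class ModelComparison:
    """Per-model fit records, ranked by the stated criterion."""

    records: Mapping[str, ModelFitRecord]
    failures: Mapping[str, str]
    best_model: str
    criterion: str


def _window_mask(t: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.ones_like(t, dtype=bool)
    lo, hi = window
    return (t >= lo) & (t <= hi)


def _ols(x: np.ndarray, y: np.ndarray, window: tuple[float, float]) -> LinearFit:
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        r_squared=float(res.rvalue**2),
        n_points=int(x.size),
        window=window,
    )


def loglog_powerlaw_fit(
    profile: ReleaseProfile, window: tuple[float, float] | None = None
) -> LinearFit:
    """OLS of ln(release) on ln(time); the slope is the power-law exponent n.

    Points with ``t <= 0`` or ``release <= 0`` are excluded (with a logged
    warning) since they cannot be log-transformed.
    """
    t, r = profile.times, profile.release
    mask = _window_mask(t, window) & (t > 0) & (r > 0)
    n_dropped = int(np.count_nonzero(_window_mask(t, window)) - np.count_nonzero(mask))
    if n_dropped:
        logger.warning(
            "loglog_powerlaw_fit: excluded %d non-positive point(s)", n_dropped
        )
    if np.count_nonzero(mask) < 3:
        raise FitError("fewer than 3 usable points for log-log regression")
    tt, rr = t[mask], r[mask]
    return _ols(np.log(tt), np.log(rr), (float(tt[0]), float(tt[-1])))


def default_powerlaw_window(
    profile: ReleaseProfile, fraction: float = 0.6
) -> tuple[float, float]:
    """Largest initial time window with release below ``fraction`` of plateau.

    The standard power-law validity bound is 60% of the saturation value;
    ``fraction`` makes it configurable.
    """
    if not 0 < fraction <= 1:
        raise DomainError("fraction must be in (0, 1]")
    limit = fraction * profile.plateau
    ok = profile.release <= limit
    if not ok[0]:
        raise FitError(
            f"no initial points with release <= {limit:.3g}% "
            f"({fraction:.0%} of plateau {profile.plateau:.3g}%)"
        )
    # largest initial run of qualifying points
    end = int(np.argmin(ok)) if not ok.all() else len(profile)
    return (float(profile.times[0]), float(profile.times[end - 1]))


def weibull_plot_transform(
    profile: ReleaseProfile,
    m_inf: float,
    release_fraction_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Transform to Weibull-plot coordinates.

    Returns ``(x, y, n_excluded)`` with ``x = ln t`` and
    ``y = ln(-ln(1 - M/m_inf))``.  Points with ``t <= 0``, ``release <= 0``
    or ``release >= m_inf`` cannot be transformed and are excluded; their
    count is reported.

    ``release_fraction_range`` optionally restricts the transform to points
    with ``release/m_inf`` inside the given band (e.g. ``(0.1, 0.9)``).  The
    double-log transform amplifies measurement noise without bound as the
    release approaches 0 or the plateau, so trimming the tails is advisable
    on noisy data; by default all transformable points are kept.
    """
    if not m_inf > 0:
        raise DomainError("m_inf must be > 0")
    t, r = profile.times, profile.release
    mask = (t > 0) & (r > 0) & (r < m_inf)
    if release_fraction_range is not None:
        lo, hi = release_fraction_range
        if not 0 <= lo < hi <= 1:
            raise DomainError("release_fraction_range must satisfy 0 <= lo < hi <= 1")
        mask &= (r >= lo * m_inf) & (r <= hi * m_inf)
    n_excluded = int(t.size - np.count_nonzero(mask))
    if np.count_nonzero(mask) < 3:
        raise FitError("fewer than 3 transformable points for the Weibull plot")
    x = np.log(t[mask])
    y = np.log(-np.log1p(-r[mask] / m_inf))
    return x, y, n_excluded


def weibull_plot_fit(
    profile: ReleaseProfile,
    m_inf: float,
    release_fraction_range: tuple[float, float] | None = None,
) -> WeibullPlotFit:
    """OLS on the Weibull-plot transform.

    For data following the Weibull CDF exactly, the slope equals ``beta``
    and the intercept equals ``-beta * ln(tau_k)``; the derived starting
    values ``beta0`` and ``tau_k0`` seed the nonlinear fit.  See
    :func:`weibull_plot_transform` for ``release_fraction_range``.
    """
    x, y, n_excluded = weibull_plot_transform(profile, m_inf, release_fraction_range)
    base = _ols(x, y, (float(np.exp(x[0])), float(np.exp(x[-1]))))
    beta0 = base.slope
    tau_k0 = float(np.exp(-base.intercept / base.slope)) if base.slope != 0 else float(
        "nan"
    )
    return WeibullPlotFit(
        **vars(base), beta0=beta0, tau_k0=tau_k0, n_excluded=n_excluded
    )


def goodness_of_fit(
    observed: ReleaseProfile | Sequence[float],
    predicted: Sequence[float],
    n_params: int = 2,
) -> tuple[float, float, float]:
    """Return ``(r_squared, rmse, aicc)`` for predictions vs observations.

    ``aicc`` uses the least-squares form ``n*ln(RSS/n) + 2k + 2k(k+1)/(n-k-1)``
    with ``k = n_params``; it is ``inf`` when ``n <= k + 1``.  With
    zero-variance observations R^2 is undefined and reported as ``nan``.
    """
    obs = np.asarray(
        observed.release if isinstance(observed, ReleaseProfile) else observed,
        dtype=float,
    )
    pred = np.asarray(predicted, dtype=float)
    if obs.size != pred.size or obs.size < 3:
        raise DomainError("observed and predicted must be equal length >= 3")
    n = obs.size
    rss = float(np.sum((obs - pred) ** 2))
    tss = float(np.sum((obs - obs.mean()) ** 2))
    r2 = float("nan") if tss == 0 else 1.0 - rss / tss
    rmse = float(np.sqrt(rss / n))
    k = n_params
    if n - k - 1 <= 0:
        aicc = float("inf")
    else:
        aicc = n * np.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    return r2, rmse, float(aicc)


def _initial_guess(profile: ReleaseProfile, m_inf: float) -> tuple[float, float]:
    """Starting (tau_k, beta) from the Weibull-plot linearization."""
    try:
        wp = weibull_plot_fit(profile, m_inf)
        if np.isfinite(wp.tau_k0) and wp.tau_k0 > 0 and wp.beta0 > 0:
            return wp.tau_k0, wp.beta0
    except (FitError, DomainError):
        pass
    return float(np.median(profile.times[profile.times > 0])), 1.0


def fit_weibull_cdf(
    profile: ReleaseProfile,
    m_inf: float | None = None,
    free_m_inf: bool = False,
    weights: Sequence[float] | None = None,
) -> WeibullFit:
    """Nonlinear least squares of the Weibull CDF on (time, release).

    By default ``m_inf`` is held fixed at the supplied value (or the
    profile's plateau estimate when omitted), mirroring the usual practice
    of pinning the saturation level; set ``free_m_inf=True`` to estimate it.
    Optional ``weights`` are per-point 1/sigma values for weighted least
    squares.  Initialization comes from the Weibull-plot linearization.

    Non-convergence is reported in the result (``converged=False`` with the
    solver message); it never silently returns defaults.
    """
    t, r = profile.times, profile.release
    n_free = 3 if free_m_inf else 2
    if len(profile) < n_free + 1:
        raise FitError(f"need at least {n_free + 1} points for the fit")

    sigma = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.size != t.size or np.any(w <= 0):
            raise DomainError("weights must be positive, one per point")
        sigma = 1.0 / w

    m0 = float(m_inf) if m_inf is not None else profile.plateau
    if not m0 > 0:
        raise DomainError("m_inf must be > 0")
    tau0, beta0 = _initial_guess(profile, m0)

    eps = 1e-12
    if free_m_inf:
        def f(tt, m, tau, b):
            return weibull_cdf(np.asarray(tt), WeibullParams(m, tau, b))

        p0 = [max(m0, eps), tau0, beta0]
        bounds = ([eps, eps, eps], [np.inf, np.inf, np.inf])
        names = ["m_inf", "tau_k", "beta"]
    else:
        def f(tt, tau, b):
            return weibull_cdf(np.asarray(tt), WeibullParams(m0, tau, b))

        p0 = [tau0, beta0]
        bounds = ([eps, eps], [np.inf, np.inf])
        names = ["tau_k", "beta"]

    converged, message, nfev = True, "converged", 0
    try:
        popt, pcov, info, msg, ier = optimize.curve_fit(
            f,
            t,
            r,
            p0=p0,
            sigma=sigma,
            bounds=bounds,
            method="trf",
            xtol=_XTOL,
            max_nfev=_MAX_NFEV,
            full_output=True,
        )
        nfev = int(info.get("nfev", 0))
        if ier not in (1, 2, 3, 4):
            converged, message = False, str(msg)
    except RuntimeError as exc:  # solver hit max_nfev without converging
        converged, message = False, str(exc)
        popt = np.asarray(p0, dtype=float)
        pcov = np.full((len(p0), len(p0)), np.nan)
        nfev = _MAX_NFEV

    ses = {k: float(v) for k, v in zip(names, np.sqrt(np.diag(pcov)))}
    popt = [float(v) for v in popt]
    params = (
        WeibullParams(*popt) if free_m_inf else WeibullParams(m0, popt[0], popt[1])
    )
    pred = weibull_cdf(t, params)
    r2, rmse, aicc = goodness_of_fit(r, pred, n_params=n_free)
    return WeibullFit(
        params=params,
        param_ses=ses,
        m_inf_fixed=not free_m_inf,
        residual_rmse=rmse,
        r_squared=r2,
        aicc=aicc,
        converged=converged,
        n_evaluations=nfev,
        message=message,
    )


def _fit_zero_order(t, r) -> MechModelCoeffs:
    k0 = float(np.dot(t, r) / np.dot(t, t))  # LSQ through the origin
    if k0 <= 0:
        raise FitError("zero-order rate constant came out non-positive")
    return MechModelCoeffs("zero_order", (k0,))


def _fit_higuchi(t, r) -> MechModelCoeffs:
    s = np.sqrt(t)
    kh = float(np.dot(s, r) / np.dot(s, s))
    if kh <= 0:
        raise FitError("Higuchi constant came out non-positive")
    return MechModelCoeffs("higuchi", (kh,))


def _fit_first_order(t, r) -> MechModelCoeffs:
    plateau0 = max(float(np.max(r)), 1e-6)
    k0 = 1.0 / max(float(np.median(t[t > 0])), 1e-6)
    popt, _ = optimize.curve_fit(
        lambda tt, k, m: m * (-np.expm1(-k * tt)),
        t,
        r,
        p0=[k0, plateau0],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        method="trf",
        max_nfev=_MAX_NFEV,
    )
    return MechModelCoeffs("first_order", tuple(popt))


def _fit_power_law(t, r) -> MechModelCoeffs:
    pos = (t > 0) & (r > 0)
    if np.count_nonzero(pos) >= 3:
        sl, ic = np.polyfit(np.log(t[pos]), np.log(r[pos]), 1)
        p0 = [float(np.exp(ic)), float(sl)]
        if p0[0] <= 0 or p0[1] <= 0:
            p0 = [1.0, 1.0]
    else:
        p0 = [1.0, 1.0]
    popt, _ = optimize.curve_fit(
        lambda tt, k, n: k * tt**n,
        t,
        r,
        p0=p0,
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        method="trf",
        max_nfev=_MAX_NFEV,
    )
    return MechModelCoeffs("power_law", tuple(popt))


def compare_models(
    profile: ReleaseProfile,
    candidates: Sequence[str] = MODEL_IDS,
    criterion: str = "aicc",
    m_inf: float | None = None,
) -> ModelComparison:
    """Fit every candidate model and rank them by the chosen criterion.

    ``criterion`` is ``"aicc"`` (default), ``"rmse"`` or ``"r_squared"``.
    Individual model failures are recorded and the comparison proceeds with
    the survivors.
    """
    if criterion not in ("aicc", "rmse", "r_squared"):
        raise DomainError(f"unknown criterion {criterion!r}")
    unknown = set(candidates) - set(MODEL_IDS)
    if unknown:
        raise DomainError(f"unknown model id(s): {sorted(unknown)}")
    if not candidates:
        raise DomainError("need at least one candidate model")

    t, r = profile.times, profile.release
    records: dict[str, ModelFitRecord] = {}
    failures: dict[str, str] = {}
    for mid in candidates:
        try:
            if mid == "zero_order":
                coeffs = _fit_zero_order(t, r)
            elif mid == "higuchi":
                coeffs = _fit_higuchi(t, r)
            elif mid == "first_order":
                coeffs = _fit_first_order(t, r)
            elif mid == "power_law":
                coeffs = _fit_power_law(t, r)
            else:  # weibull
                wf = fit_weibull_cdf(profile, m_inf=m_inf, free_m_inf=m_inf is None)
                if not wf.converged:
                    raise FitError(f"weibull fit did not converge: {wf.message}")
                coeffs = MechModelCoeffs("weibull", wf.params.as_tuple())
            pred = model_value(coeffs, t)
            k = len(coeffs.coefficients)
            r2, rmse, aicc = goodness_of_fit(r, pred, n_params=k)
            records[mid] = ModelFitRecord(coeffs, r2, rmse, aicc)
        except (FitError, DomainError, RuntimeError) as exc:
            failures[mid] = str(exc)
            logger.warning("model %s failed to fit: %s", mid, exc)

    if not records:
        raise FitError("every candidate model failed to fit")
    if criterion == "r_squared":
        best = max(records, key=lambda m: records[m].r_squared)
    else:
        best = min(records, key=lambda m: getattr(records[m], criterion))
    return ModelComparison(
        records=records, failures=failures, best_model=best, criterion=criterion
    )
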