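"""Regulatory-style summary metrics computed from a fitted Weibull model.

Dissolution efficiency (DE) is the area under the cumulative release curve
up to a final time ``t_f``, normalized by the rectangle of 100% release over
the same span.  With release in percent this reduces to

    DE(%) = (1 / t_f) * integral_0^{t_f} M(t) dt

evaluated here by adaptive quadrature.  Also provided: time-to-percent
released (CDF inversion), a summary-table builder pairing fixed times and
release targets with their DE values, and the loading/encapsulation
percentage utilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from scipy.integrate import quad

from .errors import DomainError, UnreachableReleaseError
from .models import WeibullParams, weibull_cdf, weibull_inverse

__all__ = [
    "DEResult",
    "ReleaseTableRow",
    "ReleaseTable",
    "dissolution_efficiency",
    "time_to_release",
    "build_release_table",
    "drug_loading",
    "encapsulation_efficiency",
]

_QUAD_ABS_TOL = 1e-8


@dataclass(frozen=True)
class DEResult:
    """Dissolution efficiency at a final time ``t_f``."""

    t_f: float  # hours
    de_percent: float
    release_at_tf: float  # model release at t_f, percent
    quadrature_abs_err: float


@dataclass(frozen=True)
class ReleaseTableRow:
    """One (time, release, DE) row; ``kind`` records how it was anchored."""

    time_h: float
    release_pct: float
    de_pct: float
    kind: str  # "fixed_time" | "release_target"
    valid: bool = True
    note: str = ""


@dataclass(frozen=True)
class ReleaseTable:
    """Time-ordered (time, release, DE) rows for one named system."""

    system: str
    rows: tuple[ReleaseTableRow, ...] = field(default=())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "time_h": r.time_h,
                    "release_pct": r.release_pct,
                    "de_pct": r.de_pct,
                    "kind": r.kind,
                    "valid": r.valid,
                }
                for r in self.rows
            ]
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def dissolution_efficiency(p: WeibullParams, t_f: float) -> DEResult:
    """Dissolution efficiency DE(%) = (1/t_f) * int_0^{t_f} M(t) dt.

    Adaptive quadrature with absolute tolerance 1e-8.  The integrand is the
    bounded, monotone CDF, so the beta < 1 singularity of the release-speed
    density never enters.
    """
    if not t_f > 0:
        raise DomainError(f"t_f must be > 0, got {t_f}")
    area, abs_err = quad(
        lambda t: weibull_cdf(t, p), 0.0, t_f, epsabs=_QUAD_ABS_TOL, limit=200
    )
    return DEResult(
        t_f=float(t_f),
        de_percent=area / t_f,
        release_at_tf=weibull_cdf(t_f, p),
        quadrature_abs_err=abs_err / t_f,
    )


def time_to_release(p: WeibullParams, target: float) -> float:
    """Hours until cumulative release reaches ``target`` percent.

    Raises :class:`UnreachableReleaseError` when ``target >= m_inf``.
    """
    if not 0 < target:
        raise DomainError(f"target must be > 0, got {target}")
    return weibull_inverse(target, p)


def build_release_table(
    p: WeibullParams,
    fixed_times: Sequence[float] = (),
    release_targets: Sequence[float] = (),
    system: str = "",
) -> ReleaseTable:
    """Summary table pairing times, model release and DE.

    Each fixed time yields ``(t, M(t), DE(t))``; each release target yields
    ``(time_to_release, target, DE at that time)``.  Unreachable targets
    produce an invalid row (with the reason) instead of aborting the table.
    Rows are merged and sorted by time; raw unrounded values are stored.
    """
    if not fixed_times and not release_targets:
        raise DomainError("need at least one fixed time or release target")
    rows: list[ReleaseTableRow] = []
    for target in release_targets:
        try:
            t = time_to_release(p, target)
            de = dissolution_efficiency(p, t).de_percent
            rows.append(ReleaseTableRow(t, float(target), de, "release_target"))
        except (UnreachableReleaseError, DomainError) as exc:
            rows.append(
                ReleaseTableRow(
                    float("nan"), float(target), float("nan"),
                    "release_target", valid=False, note=str(exc),
                )
            )
    for t in fixed_times:
        de_res = dissolution_efficiency(p, t)
        rows.append(
            ReleaseTableRow(float(t), de_res.release_at_tf, de_res.de_percent,
                            "fixed_time")
        )
    rows.sort(key=lambda r: (float("inf") if r.time_h != r.time_h else r.time_h))
    return ReleaseTable(system=system, rows=tuple(rows))


def drug_loading(drug_mass_encapsulated: float, carrier_mass: float) -> float:
    """Drug loading percent: encapsulated drug mass over carrier mass x 100."""
    if not carrier_mass > 0:
        raise DomainError(f"carrier mass must be > 0, got {carrier_mass}")
    if drug_mass_encapsulated < 0:
        raise DomainError("encapsulated drug mass must be >= 0")
    return 100.0 * drug_mass_encapsulated / carrier_mass


def encapsulation_efficiency(
    drug_mass_encapsulated: float, drug_mass_used: float
) -> float:
    """Encapsulation efficiency percent: encapsulated over used drug mass x 100.

    Values above 100% are physically suspect (more encapsulated than used)
    and are emitted with a warning rather than rejected, since assay error
    can produce them.
    """
    if not drug_mass_used > 0:
        raise DomainError(f"drug mass used must be > 0, got {drug_mass_used}")
    if drug_mass_encapsulated < 0:
        raise DomainError("encapsulated drug mass must be >= 0")
    ee = 100.0 * drug_mass_encapsulated / drug_mass_used
    if ee > 100.0:
        warnings.warn(
            f"encapsulation efficiency {ee:.1f}% exceeds 100%", stacklevel=2
        )
    return ee
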