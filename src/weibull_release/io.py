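"""Profile CSV reading/writing and the JSON fit report.

Profile CSV dialect: comma-separated, ``.`` decimal, UTF-8, ``#`` comment
lines, one profile per file, header columns ``time_h`` and ``release_pct``.
Comment lines of the form ``# key = value`` carry provenance metadata
(ground-truth parameters, seeds) and round-trip through write/read.

Release is stored as percent on the 0-100 scale, never as a fraction; a
column maximum above 100 is rejected at parse time unless explicitly
overridden.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ProfileParseError
from .fitting import LinearFit, ReleaseProfile, WeibullFit, WeibullPlotFit
from .interpretation import MechanismLabel
from .metrics import DEResult, ReleaseTable, ReleaseTableRow
from .models import WeibullParams

__all__ = [
    "read_profile_csv",
    "write_profile_csv",
    "FitReport",
    "write_report",
    "read_report",
]

SCHEMA_VERSION = "1"
_COLUMNS = ("time_h", "release_pct")


def _parse_metadata_comments(path: Path) -> dict:
    meta: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped.startswith("#"):
                continue
            body = stripped.lstrip("#").strip()
            if "=" not in body:
                continue
            key, _, value = body.partition("=")
            key, value = key.strip(), value.strip()
            try:
                meta[key] = json.loads(value)
            except json.JSONDecodeError:
                meta[key] = value
    return meta


def read_profile_csv(path, allow_over_100: bool = False) -> ReleaseProfile:
    """Read and validate a release profile from CSV.

    Rows are sorted by time; duplicate times, negative times, non-numeric
    cells and missing columns are rejected with the offending row named.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ProfileParseError(f"{path}: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ProfileParseError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise ProfileParseError(f"{path}: no data rows")
    for col in _COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based + header line
            raise ProfileParseError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {row}"
            )
        if numeric.isna().any():
            row = int(numeric.isna().idxmax()) + 2
            raise ProfileParseError(f"{path}: empty cell in {col!r} at line {row}")
        df[col] = numeric
    if (df["time_h"] < 0).any():
        row = int((df["time_h"] < 0).idxmax()) + 2
        raise ProfileParseError(f"{path}: negative time at line {row}")
    if df["time_h"].duplicated().any():
        dup = df["time_h"][df["time_h"].duplicated()].iloc[0]
        raise ProfileParseError(f"{path}: duplicate time {dup}")
    if not allow_over_100 and float(df["release_pct"].max()) > 100.0:
        raise ProfileParseError(
            f"{path}: release_pct maximum {df['release_pct'].max()} exceeds "
            "100% — values must be percent, not fraction "
            "(pass allow_over_100=True to override)"
        )
    meta = _parse_metadata_comments(path)
    label = str(meta.pop("label", path.stem))
    m_inf_hint = meta.pop("m_inf_hint", None)
    df = df.sort_values("time_h")
    return ReleaseProfile(
        times=df["time_h"].to_numpy(),
        release=df["release_pct"].to_numpy(),
        label=label,
        m_inf_hint=float(m_inf_hint) if m_inf_hint is not None else None,
        metadata=meta,
    )


def write_profile_csv(profile: ReleaseProfile, path) -> None:
    """Write a profile with a commented provenance header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# label = {profile.label}\n")
        if profile.m_inf_hint is not None:
            fh.write(f"# m_inf_hint = {profile.m_inf_hint!r}\n")
        for key, value in profile.metadata.items():
            fh.write(f"# {key} = {json.dumps(value)}\n")
        fh.write("time_h,release_pct\n")
        for t, r in zip(profile.times, profile.release):
            fh.write(f"{float(t)!r},{float(r)!r}\n")


@dataclass(frozen=True)
class FitReport:
    """Versioned, JSON-serializable record of a full fitting run."""

    source: dict
    weibull_fit: WeibullFit | None = None
    powerlaw_fit: LinearFit | None = None
    weibull_plot: WeibullPlotFit | None = None
    mechanisms: tuple[MechanismLabel, ...] = ()
    de_results: tuple[DEResult, ...] = ()
    table: ReleaseTable | None = None
    seeds: dict = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION
    software_version: str = __version__
    timestamp: str = ""

    @staticmethod
    def now_timestamp() -> str:
        return datetime.datetime.now(datetime.timezone.utc).isoformat()

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, float) and not math.isfinite(obj):
                return repr(obj)  # "nan"/"inf" survive JSON
            if hasattr(obj, "item"):  # numpy scalar
                return obj.item()
            return obj

        return clean(
            {
                "schema_version": self.schema_version,
                "software_version": self.software_version,
                "timestamp": self.timestamp,
                "source": self.source,
                "seeds": self.seeds,
                "weibull_fit": self.weibull_fit,
                "powerlaw_fit": self.powerlaw_fit,
                "weibull_plot": self.weibull_plot,
                "mechanisms": list(self.mechanisms),
                "de_results": list(self.de_results),
                "table": self.table,
            }
        )

    @classmethod
    def from_dict(cls, d: dict) -> "FitReport":
        def num(x):
            return float(x) if isinstance(x, str) else x

        wf = d.get("weibull_fit")
        weibull_fit = (
            WeibullFit(
                params=WeibullParams(**wf["params"]),
                param_ses={k: num(v) for k, v in wf["param_ses"].items()},
                m_inf_fixed=wf["m_inf_fixed"],
                residual_rmse=num(wf["residual_rmse"]),
                r_squared=num(wf["r_squared"]),
                aicc=num(wf["aicc"]),
                converged=wf["converged"],
                n_evaluations=wf["n_evaluations"],
                message=wf["message"],
            )
            if wf
            else None
        )
        pf = d.get("powerlaw_fit")
        powerlaw_fit = (
            LinearFit(**{**pf, "window": tuple(pf["window"])}) if pf else None
        )
        wp = d.get("weibull_plot")
        weibull_plot = (
            WeibullPlotFit(**{**wp, "window": tuple(wp["window"])}) if wp else None
        )
        tbl = d.get("table")
        table = (
            ReleaseTable(
                system=tbl["system"],
                rows=tuple(
                    ReleaseTableRow(**{**row, "time_h": num(row["time_h"]),
                                       "de_pct": num(row["de_pct"])})
                    for row in tbl["rows"]
                ),
            )
            if tbl
            else None
        )
        return cls(
            source=d["source"],
            weibull_fit=weibull_fit,
            powerlaw_fit=powerlaw_fit,
            weibull_plot=weibull_plot,
            mechanisms=tuple(MechanismLabel(**m) for m in d.get("mechanisms", [])),
            de_results=tuple(DEResult(**r) for r in d.get("de_results", [])),
            table=table,
            seeds=d.get("seeds", {}),
            schema_version=d["schema_version"],
            software_version=d["software_version"],
            timestamp=d.get("timestamp", ""),
        )


def write_report(report: FitReport, path, format: str = "json") -> None:
    """Serialize a report to JSON, or its table section to CSV."""
    path = Path(path)
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "csv":
        if report.table is None:
            raise ValueError("report has no table section to write as CSV")
        report.table.to_csv(path)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path) -> FitReport:
    with open(path, "r", encoding="utf-8") as fh:
        return FitReport.from_dict(json.load(fh))
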