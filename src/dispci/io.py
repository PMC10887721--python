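"""CSV/JSON readers and writers for strata data, intervals and reports.

The strata input schema is one row per (group, age band) cell:

    group, group_order, age_band, events, person_years, weight

Groups are ordered by ``group_order`` ascending (most disadvantaged
first); the age-standard weight must repeat consistently within each
age band and the weights must sum to 1 within 1e-6.
"""

from __future__ import annotations

import json
from typing import Iterable

import numpy as np
import pandas as pd

from .classical import IntervalEstimate
from .simulation import CoverageReport
from .strata import AdjustedRates, StrataTable

__all__ = [
    "STRATA_COLUMNS",
    "read_strata_csv",
    "write_adjusted_csv",
    "write_intervals",
    "write_coverage_report",
]

STRATA_COLUMNS = ("group", "group_order", "age_band", "events",
                  "person_years", "weight")

_WEIGHT_SUM_TOL = 1e-6


def read_strata_csv(path) -> StrataTable:
    """Read and validate a strata CSV into a :class:`StrataTable`."""
    df = pd.read_csv(path)
    missing = [c for c in STRATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"strata file {path} is missing columns: {missing}")
    dup = df.duplicated(subset=["group", "age_band"])
    if dup.any():
        cell = df.loc[dup.idxmax(), ["group", "age_band"]].tolist()
        raise ValueError(f"duplicate cell row for group={cell[0]!r}, age_band={cell[1]!r}")
    if (df["events"] < 0).any():
        raise ValueError("negative event counts in strata file")

    # each age band must carry a single weight, identical across groups
    wtab = df.groupby("age_band", sort=False)["weight"].nunique()
    if (wtab > 1).any():
        band = wtab.index[wtab > 1][0]
        raise ValueError(f"inconsistent weights within age_band {band!r}")

    order = (df[["group", "group_order"]].drop_duplicates()
             .sort_values("group_order"))
    if order["group"].duplicated().any():
        raise ValueError("a group appears with multiple group_order values")
    groups = order["group"].tolist()
    bands = df["age_band"].drop_duplicates().tolist()

    wide_e = df.pivot(index="group", columns="age_band", values="events")
    wide_n = df.pivot(index="group", columns="age_band", values="person_years")
    if wide_e.isna().any().any():
        raise ValueError("incomplete grid: every (group, age_band) cell is required")
    events = wide_e.loc[groups, bands].to_numpy()
    person_years = wide_n.loc[groups, bands].to_numpy()
    weights = (df.drop_duplicates("age_band").set_index("age_band")
               .loc[bands, "weight"].to_numpy(dtype=float))
    wsum = weights.sum()
    if abs(wsum - 1.0) > _WEIGHT_SUM_TOL:
        raise ValueError(f"age weights sum to {wsum:.6g}, not 1; refusing to renormalize")
    return StrataTable(events=events, person_years=person_years,
                       weights=weights / wsum, group_labels=tuple(map(str, groups)))


def write_adjusted_csv(adjusted: AdjustedRates, path, group_labels=None,
                       rate_scale: float = 1.0) -> None:
    """Write per-group adjusted rates: group, Y, var_hat, p, z."""
    J = adjusted.Y.shape[0]
    labels = list(group_labels) if group_labels else [f"group{j+1}" for j in range(J)]
    pd.DataFrame({
        "group": labels,
        "Y": adjusted.Y * rate_scale,
        "var_hat": adjusted.var_hat * rate_scale**2,
        "p": adjusted.p,
        "z": adjusted.z,
    }).to_csv(path, index=False)


def write_intervals(intervals: Iterable[IntervalEstimate], path,
                    fmt: str = "csv", rate_scale: float = 1.0, **provenance) -> None:
    """Write intervals as CSV or JSON (JSON carries provenance keys)."""
    rows = [{"measure": iv.measure, "method": iv.method, "point": iv.point,
             "lower": iv.lower, "upper": iv.upper, "level": iv.level}
            for iv in intervals]
    if fmt == "csv":
        pd.DataFrame(rows, columns=["measure", "method", "point",
                                    "lower", "upper", "level"]).to_csv(path, index=False)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump({"intervals": rows, **provenance}, fh, indent=2)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_coverage_report(report: CoverageReport, path, fmt: str = "csv") -> None:
    """Write a coverage report; CSV mirrors the measures x methods layout,
    JSON is the long form with full provenance (seed, R, B, level)."""
    if fmt == "csv":
        # %.17g guarantees a lossless float round trip
        report.coverage.rename_axis(index="measure").to_csv(path, float_format="%.17g")
    elif fmt == "json":
        long = report.to_long()
        with open(path, "w") as fh:
            json.dump({
                "scenario": report.scenario_id, "R": report.R, "B": report.B,
                "seed": report.seed, "level": report.level,
                "coverage": long.drop(columns=["scenario", "R", "B", "seed", "level"])
                .to_dict(orient="records"),
            }, fh, indent=2)
    else:
        raise ValueError(f"unknown format {fmt!r}")
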