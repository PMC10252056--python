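"""Strip-transect density estimation from replicate drone overflights.

Each flight flies a fixed set of parallel strip transects; every deer
within a strip is assumed detected (thermal contrast against a leaf-off
winter background). A transect's density is its count divided by its strip
area, a flight's density is the mean over its transects, and the survey
estimate is the mean over flights with a flight-level percentile bootstrap
for the 95% interval. A one-way ANOVA on per-transect densities grouped by
flight tests whether flights differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._common import DensityEstimate

__all__ = [
    "TRANSECT_COLUMNS",
    "AnovaResult",
    "flight_densities",
    "drone_survey_estimate",
    "flights_anova",
]

TRANSECT_COLUMNS = ("flight_id", "transect_id", "length_km", "swath_km", "count")


def _validate_transects(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRANSECT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"transect table missing column(s) {missing}")
    t = records.copy()
    if (t["length_km"] <= 0).any() or (t["swath_km"] <= 0).any():
        raise ValueError("transect length and swath must be positive")
    if (t["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    return t


def flight_densities(
    records: pd.DataFrame, mode: str = "mean"
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-transect densities and per-flight densities (deer/km^2).

    ``mode="mean"`` (default) takes each flight's density as the unweighted
    mean of its transect densities; ``mode="pooled"`` divides the flight's
    total count by its total strip area (area-weighted), which is invariant
    to splitting a transect into sub-transects.
    """
    if mode not in {"mean", "pooled"}:
        raise ValueError("mode must be 'mean' or 'pooled'")
    t = _validate_transects(records)
    t["area_km2"] = t["length_km"] * t["swath_km"]
    t["density"] = t["count"] / t["area_km2"]
    if mode == "mean":
        flight = t.groupby("flight_id", sort=True)["density"].mean()
    else:
        g = t.groupby("flight_id", sort=True)
        flight = g["count"].sum() / g["area_km2"].sum()
    flight.name = "density"
    return t, flight


def drone_survey_estimate(
    flight_means: Sequence[float] | pd.Series,
    n_boot: int = 10_000,
    seed: int | None = None,
    area_km2: float | None = None,
    period: str = "",
) -> DensityEstimate:
    """Survey density: mean of flight densities, with a flight bootstrap CI.

    The interval is the 2.5/97.5 percentile of means of ``n_boot``
    with-replacement resamples of the flight densities. With a single
    flight only the point estimate is meaningful and the interval collapses
    onto it.
    """
    means = np.asarray(flight_means, dtype=float)
    if means.size < 1:
        raise ValueError("need at least one flight")
    density = float(means.mean())
    if means.size >= 2:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, means.size, size=(n_boot, means.size))
        boot = means[idx].mean(axis=1)
        lo, hi = np.percentile(boot, [2.5, 97.5])
    else:
        lo = hi = density
    return DensityEstimate(
        method="drone",
        period=period,
        density=density,
        ci_low=float(min(lo, density)),
        ci_high=float(max(hi, density)),
        area_km2=float(area_km2) if area_km2 else 1.375,
        extra={"n_flights": int(means.size)},
    )


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float


def flights_anova(records: pd.DataFrame) -> AnovaResult:
    """One-way ANOVA of per-transect densities grouped by flight.

    With a single grouping factor the type II sum-of-squares decomposition
    coincides with the ordinary between/within one-way ANOVA, so the F
    statistic comes straight from that decomposition; the p-value is the
    upper tail of F(df_between, df_within).
    """
    t, _ = flight_densities(records)
    groups = [g["density"].to_numpy() for _, g in t.groupby("flight_id", sort=True)]
    if len(groups) < 2:
        raise ValueError("need at least 2 flights for ANOVA")
    n_total = sum(len(g) for g in groups)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    if df_within < 1:
        raise ValueError("not enough transects for a within-flight error term")
    res = stats.f_oneway(*groups)
    F = float(res.statistic)
    if not np.isfinite(F):  # identical groups: zero between- and within-variance
        F = 0.0
    p = float(stats.f.sf(F, df_between, df_within))
    return AnovaResult(F=F, df_between=df_between, df_within=df_within, p_value=p)
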