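"""Synthetic populations, landscapes and surveys for validating the estimators.

Everything the three estimators consume can be generated here with known
ground truth: a smoothed-noise elevation landscape with a regular camera
grid, repeated point counts obeying the binomial-Poisson mixture, photo
streams of individually identifiable males for the mark-resight ratio, and
strip-transect overflights of a uniform point process. The default
constants mirror the study design this package targets: 22 camera sites
about 636 m apart over a 10.24 km^2 region, three-month (90-occasion)
seasons, and 5 replicate drone flights over 12 parallel transects spaced
300 m apart with a 100 m swath, summing to 13.75 km of flight line
(1.375 km^2, ~13.4% of the area).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage, special
from shapely.geometry import Polygon, box

from .io_ingest import (
    CountMatrix,
    ElevationGrid,
    PhotoRecord,
    standardize_covariates,
    terrain_covariates,
)
from .mark_resight import tallies_from_photos

__all__ = [
    "PMSP_AREA_KM2",
    "PMSP_N_SITES",
    "PMSP_SPACING_M",
    "PMSP_N_OCCASIONS",
    "PMSP_N_FLIGHTS",
    "PMSP_TRANSECT_SPACING_M",
    "PMSP_SWATH_KM",
    "PMSP_TRANSECT_TOTAL_KM",
    "WINTER_BETA",
    "WINTER_ALPHA",
    "SyntheticTruth",
    "Landscape",
    "grid_spacing_for_coverage",
    "strip_area_km2",
    "pmsp_transect_layout",
    "make_landscape_and_sites",
    "calibrate_abundance_intercept",
    "simulate_nmix_counts",
    "simulate_marked_photos",
    "simulate_drone_flights",
    "pmsp_scenario",
    "PMSPScenario",
]

# Study-design constants
PMSP_AREA_KM2 = 10.24
PMSP_N_SITES = 22
PMSP_SPACING_M = 636.0
PMSP_N_OCCASIONS = 90
PMSP_N_FLIGHTS = 5
PMSP_TRANSECT_SPACING_M = 300.0
PMSP_SWATH_KM = 0.1
PMSP_TRANSECT_TOTAL_KM = 13.75
_REGION_WIDTH_KM = 2.8  # east-west extent; N-S extent follows from the area

# Winter generating truth: abundance on the log scale, detection on the
# logit scale, covariates z-scored.
WINTER_BETA = {"intercept": 2.51, "aspect_ns": -0.26, "elevation": 0.23}
WINTER_ALPHA = {"intercept": -3.19, "slope": -0.29}

_SQ_M_PER_ACRE = 4046.8564224


def grid_spacing_for_coverage(acres_per_camera: float = 100.0) -> float:
    """Camera-grid spacing (m) giving one camera per the stated acreage:
    the side of a square of that area. 100 acres -> ~636 m."""
    if acres_per_camera <= 0:
        raise ValueError("acreage must be positive")
    return math.sqrt(acres_per_camera * _SQ_M_PER_ACRE)


def strip_area_km2(layout: pd.DataFrame) -> float:
    """Total strip area (km^2) of a transect layout: sum of length x swath."""
    return float((layout["length_km"] * layout["swath_km"]).sum())


@dataclass
class SyntheticTruth:
    """Generating parameters and realized quantities of a simulation."""

    seed: int | None
    total_density_true: float
    area_km2: float
    beta_true: dict = field(default_factory=dict)
    alpha_true: dict = field(default_factory=dict)
    N_true: np.ndarray | None = None
    lambda_true: np.ndarray | None = None
    p_true: np.ndarray | None = None
    demographics: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


@dataclass
class Landscape:
    """A synthetic terrain with camera sites and derived covariates."""

    grid: ElevationGrid
    boundary: Polygon
    sites: pd.DataFrame          # site_id, x, y (metres)
    covariates: pd.DataFrame     # raw terrain covariates
    covariates_std: pd.DataFrame  # z-scored, with scaling in .attrs


def make_landscape_and_sites(
    n_sites: int = PMSP_N_SITES,
    spacing_m: float = PMSP_SPACING_M,
    area_km2: float = PMSP_AREA_KM2,
    smoothness: float = 300.0,
    seed: int | None = None,
    cellsize_m: float = 30.0,
    relief_m: float = 120.0,
    jitter_m: float = 15.0,
) -> Landscape:
    """Build a smoothed-noise elevation surface and a regular camera grid.

    The region is a rectangle of the requested area. Elevation is white
    noise smoothed with a Gaussian kernel of length-scale ``smoothness``
    (metres) and rescaled to a relief of ``relief_m``; an infinite
    smoothness yields a perfectly flat field. Sites sit on a square grid at
    ``spacing_m`` with a small uniform jitter, so nearest-neighbour
    distances stay within a few tens of metres of the nominal spacing.
    """
    rng = np.random.default_rng(seed)
    width_m = _REGION_WIDTH_KM * 1000.0
    height_m = area_km2 * 1e6 / width_m
    ncols = int(np.ceil(width_m / cellsize_m))
    nrows = int(np.ceil(height_m / cellsize_m))

    if np.isinf(smoothness):
        elev = np.full((nrows, ncols), 300.0)
    else:
        noise = rng.standard_normal((nrows, ncols))
        elev = ndimage.gaussian_filter(noise, sigma=smoothness / cellsize_m, mode="reflect")
        sd = elev.std()
        if sd > 0:
            elev = 300.0 + relief_m * (elev - elev.mean()) / (4 * sd)
    grid = ElevationGrid(data=elev, cellsize=cellsize_m, origin=(0.0, 0.0))
    boundary = box(0.0, 0.0, ncols * cellsize_m, nrows * cellsize_m)

    per_side = int(np.ceil(np.sqrt(n_sites)))
    span = (per_side - 1) * spacing_m
    margin_x = (width_m - span) / 2
    margin_y = (height_m - span) / 2
    if margin_x <= jitter_m + cellsize_m or margin_y <= jitter_m + cellsize_m:
        raise ValueError(
            f"spacing {spacing_m} m is too large to place {n_sites} sites "
            f"inside {area_km2} km^2"
        )
    positions = [
        (margin_x + cx * spacing_m, margin_y + ry * spacing_m)
        for ry in range(per_side)
        for cx in range(per_side)
    ][:n_sites]
    jitter = rng.uniform(-jitter_m, jitter_m, size=(n_sites, 2))
    sites = pd.DataFrame(
        {
            "site_id": [f"S{i + 1:02d}" for i in range(n_sites)],
            "x": [p[0] + j[0] for p, j in zip(positions, jitter)],
            "y": [p[1] + j[1] for p, j in zip(positions, jitter)],
        }
    )
    cov = terrain_covariates(grid, sites, boundary)
    if np.isinf(smoothness):
        # flat field: slope/aspect/elevation are constant and cannot be
        # z-scored; keep raw values only
        cov_std = cov.copy()
    else:
        cov_std = standardize_covariates(
            cov, ["elevation", "slope", "aspect_ns", "dist_edge"]
        )
    return Landscape(
        grid=grid, boundary=boundary, sites=sites,
        covariates=cov, covariates_std=cov_std,
    )


def _linear_predictor(
    covariates: pd.DataFrame, coefs: Mapping[str, float]
) -> np.ndarray:
    eta = np.full(len(covariates), float(coefs.get("intercept", 0.0)))
    for name, value in coefs.items():
        if name == "intercept":
            continue
        if name not in covariates.columns:
            raise ValueError(f"unknown covariate {name!r}")
        eta += value * covariates[name].to_numpy(float)
    return eta


def calibrate_abundance_intercept(
    covariates: pd.DataFrame,
    slopes: Mapping[str, float],
    target_total: float,
) -> float:
    """Abundance intercept making the expected total abundance across the
    sites equal ``target_total``, given the slope coefficients."""
    if target_total <= 0:
        raise ValueError("target total must be positive")
    eta = _linear_predictor(covariates, {**slopes, "intercept": 0.0})
    return float(np.log(target_total / np.exp(eta).sum()))


def simulate_nmix_counts(
    covariates: pd.DataFrame,
    beta: Mapping[str, float] = WINTER_BETA,
    alpha: Mapping[str, float] = WINTER_ALPHA,
    n_occasions: int = PMSP_N_OCCASIONS,
    link: str = "logit",
    seed: int | None = None,
    start_date: dt.date = dt.date(2017, 12, 1),
    area_km2: float = PMSP_AREA_KM2,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw repeated point counts from the binomial-Poisson mixture.

    Site abundance N_i ~ Poisson(exp(x_i' beta)) is drawn once (closed
    population within the season); each occasion's count is
    Binomial(N_i, p_i) with p from the detection link.
    """
    if n_occasions < 1:
        raise ValueError("need at least one occasion")
    rng = np.random.default_rng(seed)
    lam = np.exp(_linear_predictor(covariates, beta))
    if not np.all(np.isfinite(lam)):
        raise ValueError("non-finite abundance rate; check coefficients")
    eta_det = _linear_predictor(covariates, alpha)
    if link == "logit":
        p = special.expit(eta_det)
    elif link == "log":
        p = np.exp(eta_det)
        if np.any(p > 1):
            raise ValueError("log link produced p > 1")
    else:
        raise ValueError("link must be 'logit' or 'log'")
    N = rng.poisson(lam)
    counts = rng.binomial(N[:, None], p[:, None], size=(len(N), n_occasions))
    occasions = [start_date + dt.timedelta(days=j) for j in range(n_occasions)]
    cm = CountMatrix(
        site_ids=[str(s) for s in covariates["site_id"]],
        occasions=occasions,
        counts=counts.astype(float),
    )
    truth = SyntheticTruth(
        seed=seed,
        total_density_true=float(lam.sum() / area_km2),
        area_km2=area_km2,
        beta_true=dict(beta),
        alpha_true=dict(alpha),
        N_true=N,
        lambda_true=lam,
        p_true=p,
        extra={"realized_density": float(N.sum() / area_km2), "link": link},
    )
    return cm, truth


def simulate_marked_photos(
    n_males: int = 60,
    n_females: int = 120,
    n_fawns: int = 36,
    sites: Sequence[str] | None = None,
    days: int = PMSP_N_OCCASIONS,
    rate: float = 0.08,
    heterogeneity: float = 0.0,
    seed: int | None = None,
    start_date: dt.date = dt.date(2017, 12, 1),
    area_km2: float = PMSP_AREA_KM2,
) -> tuple[list[PhotoRecord], pd.DataFrame, SyntheticTruth]:
    """Simulate a photo stream of individually sighted deer.

    Each individual holds one home site (drawn uniformly) and accrues
    sightings as a Poisson process at ``rate`` per day over ``days``; with
    ``heterogeneity`` > 0 individual rates are Gamma-distributed with mean
    ``rate`` and shape 1/heterogeneity. Every sighting becomes one
    single-animal photograph at the home site; male sightings carry the
    male's identity label. Returns the records, the per-site mark-resight
    tallies, and the generating truth.
    """
    if rate < 0 or heterogeneity < 0:
        raise ValueError("rate and heterogeneity must be non-negative")
    if sites is None:
        sites = [f"S{i + 1:02d}" for i in range(PMSP_N_SITES)]
    sites = [str(s) for s in sites]
    rng = np.random.default_rng(seed)
    records: list[PhotoRecord] = []

    def sightings(n: int, cls: str) -> None:
        if n == 0 or rate == 0:
            return
        home = rng.integers(0, len(sites), size=n)
        if heterogeneity > 0:
            shape = 1.0 / heterogeneity
            rates = rng.gamma(shape, rate * heterogeneity, size=n)
        else:
            rates = np.full(n, rate)
        n_sight = rng.poisson(rates * days)
        for k in range(n):
            label = f"{cls}{k + 1:04d}"
            for _ in range(int(n_sight[k])):
                day = int(rng.integers(0, days))
                second = int(rng.integers(0, 86400))
                ts = dt.datetime.combine(
                    start_date + dt.timedelta(days=day), dt.time()
                ) + dt.timedelta(seconds=second)
                records.append(
                    PhotoRecord(
                        site_id=sites[home[k]],
                        timestamp=ts,
                        n_males=1 if cls == "M" else 0,
                        n_females=1 if cls == "F" else 0,
                        n_fawns=1 if cls == "Y" else 0,
                        n_unknown=0,
                        male_ids=frozenset({label}) if cls == "M" else None,
                    )
                )

    sightings(n_males, "M")
    sightings(n_females, "F")
    sightings(n_fawns, "Y")
    tallies = tallies_from_photos(records)
    # keep every site in the tally table even if it recorded nothing
    missing = [s for s in sites if s not in set(tallies["site_id"])]
    if missing:
        zeros = pd.DataFrame(
            {
                "site_id": missing,
                "unique_males": 0,
                "male_occurrences": 0,
                "female_occurrences": 0,
                "fawn_occurrences": 0,
            }
        )
        tallies = (
            pd.concat([tallies, zeros], ignore_index=True)
            .sort_values("site_id")
            .reset_index(drop=True)
        )
    total = n_males + n_females + n_fawns
    truth = SyntheticTruth(
        seed=seed,
        total_density_true=total / area_km2,
        area_km2=area_km2,
        demographics={"males": n_males, "females": n_females, "fawns": n_fawns},
        extra={"rate": rate, "heterogeneity": heterogeneity, "days": days},
    )
    return records, tallies, truth


def pmsp_transect_layout(
    region_width_km: float = _REGION_WIDTH_KM,
    n_transects: int = 12,
    spacing_km: float = PMSP_TRANSECT_SPACING_M / 1000.0,
    swath_km: float = PMSP_SWATH_KM,
    total_length_km: float = PMSP_TRANSECT_TOTAL_KM,
) -> pd.DataFrame:
    """East-west strip layout mirroring the drone survey design: parallel
    transects 300 m apart, 100 m swath, 13.75 km of line in total. The four
    northernmost transects are short ("aborted"), the rest share one
    length, chosen so the lengths sum to the stated total."""
    n_short = max(1, n_transects // 3)
    n_long = n_transects - n_short
    # short transects at 45% of the long length
    long_len = total_length_km / (n_long + 0.45 * n_short)
    short_len = 0.45 * long_len
    rows = []
    for k in range(n_transects):
        length = long_len if k < n_long else short_len
        rows.append(
            {
                "transect_id": f"T{k + 1:02d}",
                "y_km": 0.18 + k * spacing_km,
                "x_start_km": (region_width_km - length) / 2,
                "length_km": length,
                "swath_km": swath_km,
            }
        )
    return pd.DataFrame(rows)


def simulate_drone_flights(
    density: float,
    region: Polygon,
    transects: pd.DataFrame,
    n_flights: int = PMSP_N_FLIGHTS,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate replicate strip-transect overflights of a uniform population.

    Each flight draws an independent Poisson point process with the given
    mean density (deer redistribute between flights), counts the points
    inside each strip, and assumes perfect detection within strips.
    ``region`` is the study-area polygon (km coordinates); ``transects``
    needs columns transect_id, y_km, x_start_km, length_km, swath_km.
    """
    if len(transects) == 0:
        raise ValueError("empty strip layout")
    if density < 0:
        raise ValueError("density must be non-negative")
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = region.bounds
    area = region.area
    rows = []
    realized = []
    for f in range(n_flights):
        n_pts = rng.poisson(density * area)
        # rejection-sample uniform points inside the region polygon
        xs = np.empty(n_pts)
        ys = np.empty(n_pts)
        got = 0
        while got < n_pts:
            m = (n_pts - got) * 2 + 8
            cx = rng.uniform(minx, maxx, m)
            cy = rng.uniform(miny, maxy, m)
            keep = shapely.contains(region, shapely.points(np.c_[cx, cy]))
            k = min(int(keep.sum()), n_pts - got)
            xs[got : got + k] = cx[keep][:k]
            ys[got : got + k] = cy[keep][:k]
            got += k
        realized.append(n_pts)
        for t in transects.itertuples(index=False):
            half = t.swath_km / 2
            inside = (
                (xs >= t.x_start_km)
                & (xs <= t.x_start_km + t.length_km)
                & (ys >= t.y_km - half)
                & (ys <= t.y_km + half)
            )
            rows.append(
                {
                    "flight_id": f"F{f + 1}",
                    "transect_id": t.transect_id,
                    "length_km": t.length_km,
                    "swath_km": t.swath_km,
                    "count": int(inside.sum()),
                }
            )
    records = pd.DataFrame(rows)
    truth = SyntheticTruth(
        seed=seed,
        total_density_true=float(density),
        area_km2=float(area),
        extra={"realized_N": realized, "n_flights": n_flights},
    )
    return records, truth


@dataclass
class PMSPScenario:
    """One coherent synthetic survey: a shared true density observed by all
    three methods over the same landscape."""

    landscape: Landscape
    counts: CountMatrix
    nmix_truth: SyntheticTruth
    photos: list[PhotoRecord]
    tallies: pd.DataFrame
    mark_resight_truth: SyntheticTruth
    transects: pd.DataFrame
    drone_truth: SyntheticTruth
    area_km2: float
    density_true: float
    transect_layout: pd.DataFrame


def pmsp_scenario(
    seed: int,
    beta: Mapping[str, float] = WINTER_BETA,
    alpha: Mapping[str, float] = WINTER_ALPHA,
    sighting_rate: float = 0.08,
) -> PMSPScenario:
    """Generate the full study-design scenario under one shared population.

    The abundance coefficients set the expected camera-site abundances; the
    implied total over the 10.24 km^2 area defines the scenario's true
    density, which the mark-resight population size and the drone point
    process then share. Sub-seeds for the four generators derive
    deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    subseeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]
    land = make_landscape_and_sites(seed=subseeds[0])
    counts, nmix_truth = simulate_nmix_counts(
        land.covariates_std, beta=beta, alpha=alpha, seed=subseeds[1]
    )
    density_true = nmix_truth.total_density_true
    total = density_true * PMSP_AREA_KM2
    # demographic split 1 male : 2 females : 0.6 fawns
    n_males = int(round(total / 3.6))
    n_females = int(round(2 * total / 3.6))
    n_fawns = int(round(total - n_males - n_females))
    photos, tallies, mr_truth = simulate_marked_photos(
        n_males=n_males,
        n_females=n_females,
        n_fawns=n_fawns,
        sites=list(land.covariates["site_id"]),
        rate=sighting_rate,
        seed=subseeds[2],
    )
    height_km = PMSP_AREA_KM2 / _REGION_WIDTH_KM
    region = box(0.0, 0.0, _REGION_WIDTH_KM, height_km)
    layout = pmsp_transect_layout()
    transects, drone_truth = simulate_drone_flights(
        density=density_true, region=region, transects=layout, seed=subseeds[3]
    )
    return PMSPScenario(
        landscape=land,
        counts=counts,
        nmix_truth=nmix_truth,
        photos=photos,
        tallies=tallies,
        mark_resight_truth=mr_truth,
        transects=transects,
        drone_truth=drone_truth,
        area_km2=PMSP_AREA_KM2,
        density_true=density_true,
        transect_layout=layout,
    )
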