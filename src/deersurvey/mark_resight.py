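"""Mark-resight ratio estimator of deer density from camera-trap tallies.

Antlered males are individually identifiable from their antler
characteristics, so the ratio of unique males to total male photographic
occurrences (the "population factor") estimates the sightings-per-unique-
individual rate. Multiplying female and fawn occurrence totals by that
factor converts them to unique-individual scales, and a multiplicative
extrapolation factor corrects for animals never photographed:

    factor          = unique males / male occurrences
    unique females  = factor * female occurrences
    unique fawns    = factor * fawn occurrences
    population      = extrapolation * (unique males + females + fawns)
    density         = population / area

The 95% interval comes from a percentile bootstrap that resamples camera
sites with replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from ._common import DensityEstimate
from .io_ingest import PhotoRecord

logger = logging.getLogger("deersurvey")

__all__ = [
    "TALLY_COLUMNS",
    "MarkResightResult",
    "tallies_from_photos",
    "mark_resight_estimate",
    "bootstrap_mark_resight_ci",
]

TALLY_COLUMNS = (
    "site_id", "unique_males", "male_occurrences",
    "female_occurrences", "fawn_occurrences",
)


def _validate_tallies(tallies: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TALLY_COLUMNS if c not in tallies.columns]
    if missing:
        raise ValueError(f"tally table missing column(s) {missing}")
    t = tallies.copy()
    num = list(TALLY_COLUMNS[1:])
    if (t[num] < 0).any().any():
        raise ValueError("tally counts must be non-negative")
    if (t["unique_males"] > t["male_occurrences"]).any():
        raise ValueError("unique_males cannot exceed male_occurrences")
    return t


def tallies_from_photos(
    records: Iterable[PhotoRecord], dedupe: str = "site"
) -> pd.DataFrame:
    """Aggregate photo records into per-site mark-resight tallies.

    ``dedupe`` controls how a male resighted at more than one site enters
    the unique-male count: ``"site"`` (default) deduplicates identities
    within each site and sums across sites, matching a site-resampling
    bootstrap under the survey design's low cross-site capture probability;
    ``"global"`` counts each identity once park-wide (assigned to the site
    of its first sighting) for sensitivity analysis.
    """
    if dedupe not in {"site", "global"}:
        raise ValueError("dedupe must be 'site' or 'global'")
    per_site: dict[str, dict[str, float]] = {}
    ids_by_site: dict[str, set[str]] = {}
    seen_global: set[str] = set()
    for rec in sorted(records, key=lambda r: (r.timestamp, r.site_id)):
        row = per_site.setdefault(
            rec.site_id,
            {"male_occurrences": 0, "female_occurrences": 0, "fawn_occurrences": 0},
        )
        row["male_occurrences"] += rec.n_males
        row["female_occurrences"] += rec.n_females
        row["fawn_occurrences"] += rec.n_fawns
        if rec.male_ids:
            site_ids = ids_by_site.setdefault(rec.site_id, set())
            for label in rec.male_ids:
                if dedupe == "site":
                    site_ids.add(label)
                elif label not in seen_global:
                    seen_global.add(label)
                    site_ids.add(label)
    rows = []
    for site, row in sorted(per_site.items()):
        rows.append(
            {
                "site_id": site,
                "unique_males": len(ids_by_site.get(site, set())),
                **row,
            }
        )
    return pd.DataFrame(rows, columns=list(TALLY_COLUMNS))


@dataclass(frozen=True)
class MarkResightResult:
    """Density estimate with the component breakdown of the ratio method."""

    factor: float
    unique_males: float
    unique_females: float
    unique_fawns: float
    population: float
    density: float
    extrapolation: float
    area_km2: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def mark_resight_estimate(
    tallies: pd.DataFrame,
    extrapolation: float = 1.10,
    area_km2: float = 10.24,
) -> MarkResightResult:
    """Point estimate of population size and density from aggregated tallies.

    Tallies are summed over sites before the ratio is formed. Raises if the
    aggregate male occurrence count is zero (the population factor is then
    undefined).
    """
    t = _validate_tallies(tallies)
    if extrapolation <= 0:
        raise ValueError("extrapolation factor must be positive")
    if area_km2 <= 0:
        raise ValueError("area must be positive")
    um = float(t["unique_males"].sum())
    mo = float(t["male_occurrences"].sum())
    if mo == 0:
        raise ValueError("population factor undefined: zero male occurrences")
    factor = um / mo
    uf = factor * float(t["female_occurrences"].sum())
    uy = factor * float(t["fawn_occurrences"].sum())
    population = extrapolation * (um + uf + uy)
    return MarkResightResult(
        factor=factor,
        unique_males=um,
        unique_females=uf,
        unique_fawns=uy,
        population=population,
        density=population / area_km2,
        extrapolation=extrapolation,
        area_km2=area_km2,
    )


def bootstrap_mark_resight_ci(
    tallies: pd.DataFrame,
    extrapolation: float = 1.10,
    area_km2: float = 10.24,
    n_boot: int = 10_000,
    seed: int | None = None,
    period: str = "",
) -> tuple[DensityEstimate, np.ndarray]:
    """Site-resampling percentile bootstrap of the mark-resight density.

    Each replicate draws n sites with replacement, aggregates their
    tallies, and applies the ratio estimator; the interval is the 2.5/97.5
    percentile of the replicate densities. Replicates whose aggregate male
    occurrences are zero (possible with sparse sites) leave the estimator
    undefined and are redrawn; the redraw count is logged.

    Returns the density estimate (with interval) and the replicate array.
    """
    t = _validate_tallies(tallies)
    if len(t) < 2:
        raise ValueError("need at least 2 sites to bootstrap")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if float(t["male_occurrences"].sum()) == 0:
        raise ValueError("all sites have zero male occurrences")
    point = mark_resight_estimate(t, extrapolation, area_km2)
    rng = np.random.default_rng(seed)
    n = len(t)
    um = t["unique_males"].to_numpy(float)
    mo = t["male_occurrences"].to_numpy(float)
    fo = t["female_occurrences"].to_numpy(float)
    yo = t["fawn_occurrences"].to_numpy(float)
    densities = np.empty(n_boot)
    filled = 0
    redraws = 0
    while filled < n_boot:
        todo = n_boot - filled
        idx = rng.integers(0, n, size=(todo, n))
        MO = mo[idx].sum(axis=1)
        ok = MO > 0
        redraws += int((~ok).sum())
        UM = um[idx[ok]].sum(axis=1)
        FO = fo[idx[ok]].sum(axis=1)
        YO = yo[idx[ok]].sum(axis=1)
        factor = UM / MO[ok]
        pop = extrapolation * (UM + factor * FO + factor * YO)
        k = int(ok.sum())
        densities[filled : filled + k] = pop / area_km2
        filled += k
    if redraws:
        logger.info("bootstrap_mark_resight_ci: redrew %d replicate(s)", redraws)
    lo, hi = np.percentile(densities, [2.5, 97.5])
    est = DensityEstimate(
        method="mark_resight",
        period=period,
        density=point.density,
        ci_low=float(min(lo, point.density)),
        ci_high=float(max(hi, point.density)),
        area_km2=area_km2,
        extra={"redraws": redraws, "factor": point.factor},
    )
    return est, densities
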