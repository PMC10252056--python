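"""Ingest camera-trap records and terrain, build daily-maximum count matrices.

Camera-trap photographs arrive pre-classified as tabular rows (site,
timestamp, per-class deer counts, optional identities of antlered males).
This module validates them, collapses them to one count per site per day
(the highest total in any single photograph, which guards against
repeat-counting the same animals within a day), bins occasions into
three-month seasons, and derives site covariates (elevation, slope,
north-south aspect component, distance to the study-area edge) from a
gridded elevation surface.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

logger = logging.getLogger("deersurvey")

__all__ = [
    "PhotoRecord",
    "Season",
    "CountMatrix",
    "ElevationGrid",
    "SchemaError",
    "ValidationError",
    "read_photo_records",
    "daily_max_count_matrix",
    "season_of",
    "cosine_aspect",
    "horn_slope_aspect",
    "terrain_covariates",
    "standardize_covariates",
]


class SchemaError(ValueError):
    """An input file is missing a required column."""


class ValidationError(ValueError):
    """One or more input rows violate a field invariant."""


# ---------------------------------------------------------------------------
# Photo records
# ---------------------------------------------------------------------------

PHOTO_COLUMNS = ("site_id", "timestamp", "n_males", "n_females", "n_fawns", "n_unknown")


@dataclass(frozen=True)
class PhotoRecord:
    """One camera-trap photograph's classification.

    ``male_ids`` carries the identity labels of individually recognisable
    antlered males visible in the photograph, when such labels exist.
    """

    site_id: str
    timestamp: dt.datetime
    n_males: int
    n_females: int
    n_fawns: int
    n_unknown: int
    male_ids: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for name in ("n_males", "n_females", "n_fawns", "n_unknown"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.male_ids is not None and len(self.male_ids) > self.n_males:
            raise ValidationError(
                f"{len(self.male_ids)} male identities exceed n_males={self.n_males}"
            )

    @property
    def total(self) -> int:
        """All deer in the photograph, regardless of demographic class."""
        return self.n_males + self.n_females + self.n_fawns + self.n_unknown

    @property
    def date(self) -> dt.date:
        return self.timestamp.date()


def read_photo_records(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    delimiter: str = ",",
    study_window: tuple[dt.date, dt.date] | None = None,
) -> list[PhotoRecord]:
    """Read photo-classification rows from a delimited text file.

    Parameters
    ----------
    path : path
        Delimited file with a header row. Required columns (or their
        renamings via ``schema``): site_id, timestamp (ISO-8601), n_males,
        n_females, n_fawns, n_unknown. An optional ``male_id`` column holds
        semicolon-separated identity labels.
    schema : mapping, optional
        Maps canonical column names to the file's column names.
    study_window : (date, date), optional
        If given, timestamps outside the closed window are validation errors.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        Listing every failing row by its 1-based data-row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)

    colmap = {name: name for name in PHOTO_COLUMNS}
    colmap["male_id"] = "male_id"
    if schema:
        colmap.update(schema)
    missing = [c for c in PHOTO_COLUMNS if colmap[c] not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing} in {path}")

    used = {colmap[c] for c in PHOTO_COLUMNS}
    has_male_id = colmap["male_id"] in df.columns
    if has_male_id:
        used.add(colmap["male_id"])
    extras = [c for c in df.columns if c not in used]
    if extras:
        logger.info("read_photo_records: ignoring extra column(s) %s", extras)

    records: list[PhotoRecord] = []
    problems: list[str] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        raw = dict(zip(df.columns, row))
        try:
            ts = pd.Timestamp(raw[colmap["timestamp"]]).to_pydatetime()
        except (ValueError, TypeError):
            problems.append(
                f"row {idx}: unparseable timestamp {raw[colmap['timestamp']]!r}"
            )
            continue
        if study_window is not None and not (
            study_window[0] <= ts.date() <= study_window[1]
        ):
            problems.append(f"row {idx}: timestamp {ts} outside study window")
            continue
        try:
            counts = {
                name: int(raw[colmap[name]])
                for name in ("n_males", "n_females", "n_fawns", "n_unknown")
            }
        except ValueError as exc:
            problems.append(f"row {idx}: non-integer count ({exc})")
            continue
        male_ids: frozenset[str] | None = None
        if has_male_id:
            labels = str(raw[colmap["male_id"]]).strip()
            if labels and labels.lower() != "nan":
                male_ids = frozenset(s.strip() for s in labels.split(";") if s.strip())
        try:
            records.append(
                PhotoRecord(
                    site_id=str(raw[colmap["site_id"]]),
                    timestamp=ts,
                    male_ids=male_ids,
                    **counts,
                )
            )
        except ValidationError as exc:
            problems.append(f"row {idx}: {exc}")
    if problems:
        raise ValidationError("; ".join(problems))
    return records


# ---------------------------------------------------------------------------
# Seasons
# ---------------------------------------------------------------------------

_SEASON_OF_MONTH = {
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
}
_SEASON_START_MONTH = {"spring": 3, "summer": 6, "autumn": 9, "winter": 12}


@dataclass(frozen=True, order=True)
class Season:
    """A three-month bin. Winter spans the year boundary and is tagged by
    its starting year, e.g. December 2017 - February 2018 -> "winter 2017/18".
    """

    start_year: int
    start_month: int
    name: str = field(compare=False)

    @property
    def label(self) -> str:
        if self.name == "winter":
            return f"winter {self.start_year}/{(self.start_year + 1) % 100:02d}"
        return f"{self.name} {self.start_year}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label

    def contains(self, date: dt.date) -> bool:
        return season_of(date) == self


def season_of(date: dt.date) -> Season:
    """Map a calendar date to its three-month season.

    Summer is June-August, autumn September-November, winter
    December-February (tagged by the December year), spring March-May.
    """
    name = _SEASON_OF_MONTH[date.month]
    start_year = date.year
    if name == "winter" and date.month in (1, 2):
        start_year -= 1
    return Season(start_year=start_year, start_month=_SEASON_START_MONTH[name], name=name)


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Sites x occasions matrix of daily maximum deer counts.

    ``counts`` is float so that missing occasions (camera inactive) can be
    NaN; present values are non-negative integers.
    """

    site_ids: list[str]
    occasions: list[dt.date]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.site_ids), len(self.occasions)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.occasions)} occasions"
            )
        occ = self.occasions
        if any(b <= a for a, b in zip(occ, occ[1:])):
            raise ValueError("occasions must be strictly increasing")
        present = self.counts[~np.isnan(self.counts)]
        if (present < 0).any():
            raise ValueError("counts must be >= 0 where present")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_occasions(self) -> int:
        return len(self.occasions)

    @property
    def seasons(self) -> list[Season]:
        """Season bin of each occasion, in occasion order."""
        return [season_of(d) for d in self.occasions]

    def season_labels(self) -> list[str]:
        return [s.label for s in self.seasons]

    def subset_season(self, season: Season | str) -> "CountMatrix":
        """Restrict occasions to one three-month season bin."""
        want = season.label if isinstance(season, Season) else season
        keep = [j for j, s in enumerate(self.seasons) if s.label == want]
        if not keep:
            raise ValueError(f"no occasions fall in season {want!r}")
        return CountMatrix(
            site_ids=list(self.site_ids),
            occasions=[self.occasions[j] for j in keep],
            counts=self.counts[:, keep],
        )

    def subset_dates(self, start: dt.date, end: dt.date) -> "CountMatrix":
        keep = [j for j, d in enumerate(self.occasions) if start <= d <= end]
        if not keep:
            raise ValueError(f"no occasions in [{start}, {end}]")
        return CountMatrix(
            site_ids=list(self.site_ids),
            occasions=[self.occasions[j] for j in keep],
            counts=self.counts[:, keep],
        )

    def max_count(self) -> int:
        present = self.counts[~np.isnan(self.counts)]
        return 0 if present.size == 0 else int(present.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.site_ids, name="site_id"),
            columns=[d.isoformat() for d in self.occasions],
        )

    def to_csv(self, path: str | Path, delimiter: str = ",") -> None:
        self.to_frame().to_csv(path, sep=delimiter)

    @classmethod
    def from_csv(cls, path: str | Path, delimiter: str = ",") -> "CountMatrix":
        df = pd.read_csv(path, sep=delimiter, index_col=0)
        occasions = [dt.date.fromisoformat(c) for c in df.columns]
        return cls(
            site_ids=[str(s) for s in df.index],
            occasions=occasions,
            counts=df.to_numpy(dtype=float),
        )


def daily_max_count_matrix(
    records: Iterable[PhotoRecord],
    sites: Sequence[str],
    dates: Sequence[dt.date],
    inactive: Mapping[str, Iterable[dt.date]] | None = None,
) -> CountMatrix:
    """Collapse photographs to one daily maximum count per site.

    Cell (i, j) holds the largest total deer count appearing in any single
    photograph at site i on day j. Days with no photographs at an operating
    camera are observed zeros; days listed in ``inactive`` for a site are
    recorded as missing (NaN).
    """
    sites = [str(s) for s in sites]
    if not sites:
        raise ValueError("sites must be non-empty")
    if len(dates) == 0:
        raise ValueError("dates must be non-empty")
    site_index = {s: i for i, s in enumerate(sites)}
    date_index = {d: j for j, d in enumerate(dates)}
    counts = np.zeros((len(sites), len(dates)))
    for rec in records:
        if rec.site_id not in site_index:
            raise ValueError(f"record at unknown site {rec.site_id!r}")
        j = date_index.get(rec.date)
        if j is None:
            continue
        i = site_index[rec.site_id]
        counts[i, j] = max(counts[i, j], rec.total)
    if inactive:
        for site, days in inactive.items():
            if site not in site_index:
                raise ValueError(f"inactive entry for unknown site {site!r}")
            for d in days:
                j = date_index.get(d)
                if j is not None:
                    counts[site_index[site], j] = np.nan
    return CountMatrix(site_ids=sites, occasions=list(dates), counts=counts)


# ---------------------------------------------------------------------------
# Terrain covariates
# ---------------------------------------------------------------------------


def cosine_aspect(aspect_deg: float | np.ndarray) -> float | np.ndarray:
    """North-south component of a compass aspect: cos(aspect).

    0 deg (north-facing) -> +1, 180 deg (south-facing) -> -1; east and west
    both map to 0, so the transform is symmetric about the N-S axis.
    """
    a = np.asarray(aspect_deg, dtype=float)
    if np.any((a < 0) | (a > 360)):
        raise ValueError("aspect must lie in [0, 360] degrees")
    out = np.cos(np.deg2rad(a))
    return float(out) if np.isscalar(aspect_deg) else out


@dataclass
class ElevationGrid:
    """Single-band elevation raster: ``data[0, 0]`` is the north-west cell,
    rows run southward, columns eastward. ``origin`` is the (x, y) of the
    lower-left corner; coordinates and ``cellsize`` share one length unit.
    """

    data: np.ndarray
    cellsize: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("elevation grid must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/column of the cell containing (x, y); raises if outside."""
        nrows, ncols = self.data.shape
        col = int((x - self.origin[0]) // self.cellsize)
        row_from_bottom = int((y - self.origin[1]) // self.cellsize)
        row = nrows - 1 - row_from_bottom
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise ValueError(f"point ({x}, {y}) lies outside the elevation grid")
        return row, col

    def to_ascii(self, path: str | Path) -> None:
        nrows, ncols = self.data.shape
        header = (
            f"ncols {ncols}\nnrows {nrows}\n"
            f"xllcorner {self.origin[0]}\nyllcorner {self.origin[1]}\n"
            f"cellsize {self.cellsize}\nNODATA_value -9999\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.data, fmt="%.6f")

    @classmethod
    def from_ascii(cls, path: str | Path) -> "ElevationGrid":
        """Read an ESRI ASCII grid (6 header lines then row-major values)."""
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, value = fh.readline().split()
                meta[key.lower()] = float(value)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        if data.shape != (int(meta["nrows"]), int(meta["ncols"])):
            raise ValueError("grid dimensions do not match header")
        return cls(
            data=data,
            cellsize=meta["cellsize"],
            origin=(meta["xllcorner"], meta["yllcorner"]),
        )


def horn_slope_aspect(grid: ElevationGrid) -> tuple[np.ndarray, np.ndarray]:
    """Slope (degrees) and downslope compass aspect (degrees) per cell.

    Uses Horn's third-order finite difference over the 3x3 neighbourhood,
    the stencil standard terrain tools apply to square-cell DEMs. Edge rows
    and columns are handled by replicating the border (one-sided
    differences). Flat cells get slope 0 and aspect NaN.
    """
    z = np.pad(grid.data, 1, mode="edge")
    cs = grid.cellsize
    # 3x3 neighbourhood of each interior cell of the padded array
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * cs)  # eastward
    dzdy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8 * cs)  # northward
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    with np.errstate(invalid="ignore"):
        aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect[(dzdx == 0) & (dzdy == 0)] = np.nan
    return slope, aspect


def terrain_covariates(
    grid: ElevationGrid,
    sites: pd.DataFrame,
    boundary: Polygon,
) -> pd.DataFrame:
    """Site covariate table from an elevation surface and a boundary polygon.

    Parameters
    ----------
    sites : DataFrame
        Columns ``site_id``, ``x``, ``y`` in the grid's coordinate system.
    boundary : shapely Polygon
        Study-region outline; ``dist_edge`` is the distance to its ring.

    Returns
    -------
    DataFrame with columns site_id, elevation, slope, aspect_ns, dist_edge.
    Flat cells get aspect_ns = 0 (no north-south component).
    """
    slope, aspect = horn_slope_aspect(grid)
    rows = []
    for rec in sites.itertuples(index=False):
        pt = Point(rec.x, rec.y)
        if not boundary.buffer(1e-9).contains(pt):
            raise ValueError(f"site {rec.site_id!r} lies outside the study boundary")
        r, c = grid.cell_of(rec.x, rec.y)
        asp = aspect[r, c]
        aspect_ns = 0.0 if np.isnan(asp) else float(cosine_aspect(asp))
        rows.append(
            {
                "site_id": str(rec.site_id),
                "elevation": float(grid.data[r, c]),
                "slope": float(slope[r, c]),
                "aspect_ns": aspect_ns,
                "dist_edge": float(boundary.exterior.distance(pt)),
            }
        )
    return pd.DataFrame(rows)


def standardize_covariates(
    table: pd.DataFrame, columns: Sequence[str]
) -> pd.DataFrame:
    """Z-score the named columns ((x - mean) / sd, sd with n-1 denominator).

    The original mean and sd of each column are retained in
    ``result.attrs["scaling"]`` for back-transformation. A constant column
    is an error because it cannot be scaled.
    """
    out = table.copy()
    scaling: dict[str, tuple[float, float]] = dict(table.attrs.get("scaling", {}))
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
        if sd == 0 or np.unique(x).size < 2:
            raise ValueError(f"column {col!r} is constant and cannot be standardized")
        out[col] = (x - mean) / sd
        scaling[col] = (mean, sd)
    out.attrs["scaling"] = scaling
    return out
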