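"""Domain types shared by every screening heuristic.

Occurrence records live in a :class:`pandas.DataFrame` with the canonical
columns in :data:`RECORD_COLUMNS`; :class:`OccurrenceRecord` is the validated
single-record view. A :class:`TargetPopulation` declares the statistical
population an analysis intends to speak about — geographic extent, temporal
extent, target taxon list — together with the grain (spatial and temporal
resolution) at which inference is stated. :class:`GridSpec` and
:class:`PeriodSpec` turn those declarations into concrete cell and period
assignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import box, shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "RECORD_COLUMNS",
    "OccurrenceRecord",
    "GridSpec",
    "PeriodSpec",
    "TargetPopulation",
    "records_to_frame",
    "assign_cell",
    "assign_period",
    "count_periods",
    "filter_to_population",
    "jaccard",
]

#: Canonical occurrence-table columns (Darwin Core semantics, short names).
RECORD_COLUMNS = ("taxon", "lon", "lat", "year", "count", "coord_uncertainty_m", "source")


@dataclass(frozen=True)
class OccurrenceRecord:
    """One detection event: a taxon at a place (WGS84 degrees) in a year."""

    taxon: str
    lon: float
    lat: float
    year: int
    count: int | None = None
    coord_uncertainty_m: float | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"lon {self.lon} outside [-180, 180]")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"lat {self.lat} outside [-90, 90]")
        if not (1000 <= int(self.year) <= 9999):
            raise ValueError(f"year {self.year} is not a 4-digit calendar year")
        if self.count is not None and self.count < 0:
            raise ValueError("count must be non-negative")
        if self.coord_uncertainty_m is not None and self.coord_uncertainty_m < 0:
            raise ValueError("coord_uncertainty_m must be non-negative")


def records_to_frame(records: Iterable[OccurrenceRecord]) -> pd.DataFrame:
    """Stack validated records into the canonical occurrence table."""
    rows = [
        (r.taxon, r.lon, r.lat, r.year, r.count, r.coord_uncertainty_m, r.source)
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid with half-open cells ``[edge, edge + res)``.

    The origin is configurable but fixed by default at (-180, -90) so that
    cell ids are reproducible across datasets rather than anchored to the
    data at hand.
    """

    resolution: float
    origin_lon: float = -180.0
    origin_lat: float = -90.0

    def __post_init__(self) -> None:
        if not self.resolution > 0:
            raise ValueError("grid resolution must be positive")

    def cell(self, lon: float, lat: float) -> tuple[int, int]:
        if not (math.isfinite(lon) and math.isfinite(lat)):
            raise ValueError("non-finite coordinate")
        col = math.floor((lon - self.origin_lon) / self.resolution)
        row = math.floor((lat - self.origin_lat) / self.resolution)
        return col, row

    def cells(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        bad = ~(np.isfinite(lon) & np.isfinite(lat))
        if bad.any():
            raise ValueError(f"non-finite coordinates at rows {np.flatnonzero(bad).tolist()}")
        col = np.floor((lon - self.origin_lon) / self.resolution).astype(int)
        row = np.floor((lat - self.origin_lat) / self.resolution).astype(int)
        return col, row


@dataclass(frozen=True)
class PeriodSpec:
    """Contiguous temporal bins of ``width`` years covering an inclusive span.

    Periods are labelled "p1", "p2", ... in chronological order.  The last
    period may be truncated by ``end_year`` (1950-2019 with width 10 gives a
    full p7 = 2010-2019; 1950-2020 gives a one-year p8), so the bins always
    partition the declared extent exactly.
    """

    start_year: int
    end_year: int
    width: int = 10

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("period width must be >= 1 year")
        if self.start_year > self.end_year:
            raise ValueError("start_year must not exceed end_year")

    @property
    def n_periods(self) -> int:
        return math.ceil((self.end_year - self.start_year + 1) / self.width)

    def index(self, year: int) -> int:
        """1-based period index; raises if the year is out of extent."""
        if not (self.start_year <= year <= self.end_year):
            raise ValueError(f"year {year} outside [{self.start_year}, {self.end_year}]")
        return 1 + (int(year) - self.start_year) // self.width

    def indices(self, years: np.ndarray) -> np.ndarray:
        years = np.asarray(years, dtype=int)
        if ((years < self.start_year) | (years > self.end_year)).any():
            raise ValueError("years outside temporal extent")
        return 1 + (years - self.start_year) // self.width

    def label(self, idx: int) -> str:
        if not 1 <= idx <= self.n_periods:
            raise ValueError(f"period index {idx} out of range")
        return f"p{idx}"

    @property
    def labels(self) -> list[str]:
        return [self.label(i) for i in range(1, self.n_periods + 1)]

    def bounds(self, idx: int) -> tuple[int, int]:
        """Inclusive (first_year, last_year) of period ``idx``."""
        if not 1 <= idx <= self.n_periods:
            raise ValueError(f"period index {idx} out of range")
        first = self.start_year + (idx - 1) * self.width
        last = min(first + self.width - 1, self.end_year)
        return first, last


def assign_cell(record: OccurrenceRecord, grid: GridSpec) -> tuple[int, int]:
    """Cell id (col, row) of a record under the grid's half-open convention."""
    return grid.cell(record.lon, record.lat)


def assign_period(year: int, periods: PeriodSpec) -> str:
    """Period label ("p1", "p2", ...) of a calendar year."""
    return periods.label(periods.index(year))


def count_periods(periods: PeriodSpec) -> int:
    """Number of temporal bins in the spec (last bin may be truncated)."""
    return periods.n_periods


def _as_geometry(geo_extent) -> BaseGeometry:
    if isinstance(geo_extent, BaseGeometry):
        return geo_extent
    if isinstance(geo_extent, Mapping):  # GeoJSON geometry
        return shape(geo_extent)
    seq = tuple(geo_extent)
    if len(seq) == 4:  # (min_lon, min_lat, max_lon, max_lat)
        return box(*seq)
    raise ValueError("geo_extent must be a geometry, GeoJSON mapping or 4-number bbox")


@dataclass(frozen=True)
class TargetPopulation:
    """The declared statistical target population of an analysis.

    Extents over geography, time and taxonomy, plus the resolutions (grain
    sizes) at which inference is desired. Environmental axes are optional
    named covariates assessed per grid cell.
    """

    geo_extent: BaseGeometry
    temporal_extent: tuple[int, int]
    taxa: tuple[str, ...]
    spatial_resolution: float
    temporal_resolution: int
    env_axes: tuple[str, ...] = ()
    grid_origin: tuple[float, float] = (-180.0, -90.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "geo_extent", _as_geometry(self.geo_extent))
        object.__setattr__(self, "temporal_extent", tuple(int(y) for y in self.temporal_extent))
        object.__setattr__(self, "taxa", tuple(self.taxa))
        object.__setattr__(self, "env_axes", tuple(self.env_axes))
        y0, y1 = self.temporal_extent
        if y0 > y1:
            raise ValueError("temporal_extent start exceeds end")
        if not self.spatial_resolution > 0:
            raise ValueError("spatial_resolution must be positive")
        if self.temporal_resolution < 1:
            raise ValueError("temporal_resolution must be >= 1 year")
        if not self.taxa:
            raise ValueError("taxa list must be non-empty")
        if not self.geo_extent.area > 0:
            raise ValueError("geo_extent must have positive area")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            resolution=self.spatial_resolution,
            origin_lon=self.grid_origin[0],
            origin_lat=self.grid_origin[1],
        )

    @property
    def periods(self) -> PeriodSpec:
        return PeriodSpec(self.temporal_extent[0], self.temporal_extent[1], self.temporal_resolution)

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "TargetPopulation":
        geo = cfg.get("geo_extent")
        if geo is None:
            raise ValueError("population config missing 'geo_extent'")
        kwargs = {}
        if "grid_origin" in cfg:
            kwargs["grid_origin"] = tuple(cfg["grid_origin"])
        return cls(
            geo_extent=geo,
            temporal_extent=tuple(cfg["temporal_extent"]),
            taxa=tuple(cfg["taxa"]),
            spatial_resolution=float(cfg["spatial_resolution"]),
            temporal_resolution=int(cfg.get("temporal_resolution", 1)),
            env_axes=tuple(cfg.get("env_axes", ())),
            **kwargs,
        )

    @classmethod
    def from_config(cls, path) -> "TargetPopulation":
        """Load a population declaration from a YAML config file."""
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, Mapping):
            raise ValueError(f"population config {path} is not a mapping")
        return cls.from_dict(cfg)

    def to_dict(self) -> dict:
        return {
            "geo_extent_wkt": self.geo_extent.wkt,
            "temporal_extent": list(self.temporal_extent),
            "taxa": list(self.taxa),
            "spatial_resolution": float(self.spatial_resolution),
            "temporal_resolution": int(self.temporal_resolution),
            "env_axes": list(self.env_axes),
            "grid_origin": list(self.grid_origin),
        }


def filter_to_population(
    records: pd.DataFrame, pop: TargetPopulation
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Restrict records to the target population.

    A record is excluded for the *first* failing reason in the fixed order
    geo -> time -> taxon, so the tally is deterministic. Returns the retained
    records (index reset) and the exclusion tally.
    """
    df = records.reset_index(drop=True)
    n = len(df)
    tally = {"geo": 0, "time": 0, "taxon": 0}
    if n == 0:
        return df, tally
    in_geo = shapely.intersects_xy(
        pop.geo_extent, df["lon"].to_numpy(float), df["lat"].to_numpy(float)
    )
    y0, y1 = pop.temporal_extent
    years = df["year"].to_numpy()
    in_time = (years >= y0) & (years <= y1)
    in_taxa = df["taxon"].isin(pop.taxa).to_numpy()

    tally["geo"] = int((~in_geo).sum())
    tally["time"] = int((in_geo & ~in_time).sum())
    tally["taxon"] = int((in_geo & in_time & ~in_taxa).sum())
    keep = in_geo & in_time & in_taxa
    return df.loc[keep].reset_index(drop=True), tally


def jaccard(a: set, b: set) -> float | None:
    """Jaccard similarity |a∩b| / |a∪b|; ``None`` when both sets are empty.

    Single source of truth for every set-overlap heuristic (cell coverage
    overlap, taxon sampling turnover).
    """
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return None
    return len(a & b) / len(union)
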