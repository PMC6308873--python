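"""Satellite-track ingestion, cleaning, and movement summaries.

Argos/Fastloc-GPS tracks of tagged animals carry three well-known error
modes near shore: positions estimated on land, physically impossible jumps,
and unresolved Argos quality ("location class Z") fixes.  The cleaning
pipeline applies, in order:

1. **land filter** — drop points whose nearest land-mask cell is land;
2. **speed filter** — forward pass dropping any point whose great-circle
   speed from the last *retained* point exceeds ``vmax`` (default 10 km/h,
   strict inequality);
3. **class filter** — drop points whose location class is in an excluded
   set (default {"Z"}).

Summaries per track mirror the usual telemetry table: number of locations,
duration in days, summed great-circle path length, and per-segment speed
mean ± sample SD; the cohort summary is the column-wise mean ± sample
(n−1) SD across tracks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LOCATION_CLASSES",
    "TrackPoint",
    "Track",
    "LandMask",
    "FilterReport",
    "TrackSummary",
    "haversine_km",
    "read_tracks",
    "write_tracks",
    "filter_land",
    "filter_speed",
    "filter_class",
    "apply_filter_pipeline",
    "summarize_track",
    "summarize_cohort",
]

EARTH_RADIUS_KM = 6371.0
LOCATION_CLASSES = ("G", "3", "2", "1", "0", "A", "B", "Z")


@dataclass(frozen=True)
class TrackPoint:
    track_id: str
    timestamp: pd.Timestamp
    lon: float
    lat: float
    loc_class: str = "G"
    source: str = "GPS"

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon < 180.0):
            raise ValueError(f"longitude {self.lon} out of [-180, 180)")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} out of [-90, 90]")
        if self.loc_class not in LOCATION_CLASSES:
            raise ValueError(f"unknown location class {self.loc_class!r}")


@dataclass
class Track:
    """Time-ordered sequence of points sharing one track_id."""

    track_id: str
    points: list[TrackPoint]

    def __post_init__(self) -> None:
        if any(p.track_id != self.track_id for p in self.points):
            raise ValueError("points belong to different tracks")
        times = [p.timestamp for p in self.points]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("track points are not time-ordered")

    def __len__(self) -> int:
        return len(self.points)

    def lonlat(self) -> np.ndarray:
        return np.array([(p.lon, p.lat) for p in self.points])


def haversine_km(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Great-circle distance in km between (lon, lat) points, spherical
    earth of radius 6371.0 km."""
    lon1, lat1 = map(math.radians, p1)
    lon2, lat2 = map(math.radians, p2)
    dlat, dlon = lat2 - lat1, lon2 - lon1
    a = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


# ---------------------------------------------------------------------------
# land mask
# ---------------------------------------------------------------------------

@dataclass
class LandMask:
    """Regular lon/lat grid of land flags.

    ``grid`` is (nrows, ncols) boolean, row 0 the NORTHERN edge (raster
    order); cell centers are at ``(xll + (j+0.5)·cell, yll + (i'+0.5)·cell)``
    with i' counted from the southern edge.  Lookup assigns a point to its
    nearest cell center; a point exactly on a cell boundary goes to the
    lower index.  Queries outside the grid raise.
    """

    grid: np.ndarray
    xll: float
    yll: float
    cell_size: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        nrows, ncols = self.grid.shape
        return (
            self.xll,
            self.yll,
            self.xll + ncols * self.cell_size,
            self.yll + nrows * self.cell_size,
        )

    def _index(self, lon: float, lat: float) -> tuple[int, int]:
        nrows, ncols = self.grid.shape
        # nearest-center with boundary ties to the lower index:
        # i = ceil(u) - 1 for u = offset / cell_size
        col = math.ceil((lon - self.xll) / self.cell_size) - 1
        row_s = math.ceil((lat - self.yll) / self.cell_size) - 1  # from south
        if not (0 <= col < ncols and 0 <= row_s < nrows):
            raise ValueError(f"point ({lon}, {lat}) outside land-mask coverage")
        return nrows - 1 - row_s, col

    def is_land(self, lon: float, lat: float) -> bool:
        i, j = self._index(lon, lat)
        return bool(self.grid[i, j])

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        nrows, _ = self.grid.shape
        lon = self.xll + (col + 0.5) * self.cell_size
        lat = self.yll + (nrows - 1 - row + 0.5) * self.cell_size
        return lon, lat

    # ESRI ASCII grid ("Arc/Info ASCII", .asc) — plain-text raster dialect:
    # 1 = land, 0 = sea.
    @classmethod
    def from_ascii_grid(cls, path: str | Path) -> "LandMask":
        lines = Path(path).read_text().strip().splitlines()
        header: dict[str, float] = {}
        body_start = 0
        for k, line in enumerate(lines):
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
                body_start = k + 1
            else:
                break
        for need in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            if need not in header:
                raise ValueError(f"ASCII grid missing header field {need}")
        rows = [list(map(float, ln.split())) for ln in lines[body_start:]]
        grid = np.array(rows)
        if grid.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError("ASCII grid body does not match header dimensions")
        return cls(
            grid=grid > 0,
            xll=header["xllcorner"],
            yll=header["yllcorner"],
            cell_size=header["cellsize"],
        )

    def to_ascii_grid(self, path: str | Path) -> None:
        nrows, ncols = self.grid.shape
        out = [
            f"ncols {ncols}", f"nrows {nrows}",
            f"xllcorner {self.xll:g}", f"yllcorner {self.yll:g}",
            f"cellsize {self.cell_size:g}", "NODATA_value -9999",
        ]
        out += [" ".join("1" if v else "0" for v in row) for row in self.grid]
        Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# track I/O
# ---------------------------------------------------------------------------

def read_tracks(path: str | Path) -> list[Track]:
    """Read the track CSV dialect (track_id, timestamp, lon, lat, loc_class,
    source; ISO-8601 UTC timestamps).  Points are sorted by time within each
    track and exact duplicate rows dropped."""
    df = pd.read_csv(path, dtype={"track_id": str, "loc_class": str})
    required = {"track_id", "timestamp", "lon", "lat"}
    if not required <= set(df.columns):
        raise ValueError(f"track CSV needs columns {sorted(required)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    df = df.drop_duplicates()
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("timestamp", kind="stable")
        pts = [
            TrackPoint(
                track_id=tid,
                timestamp=row.timestamp,
                lon=float(row.lon),
                lat=float(row.lat),
                loc_class=str(getattr(row, "loc_class", "G")),
                source=str(getattr(row, "source", "GPS")),
            )
            for row in g.itertuples()
        ]
        tracks.append(Track(tid, pts))
    return tracks


def write_tracks(tracks: Iterable[Track], path: str | Path) -> None:
    rows = [
        {
            "track_id": p.track_id,
            "timestamp": p.timestamp.isoformat(),
            "lon": p.lon,
            "lat": p.lat,
            "loc_class": p.loc_class,
            "source": p.source,
        }
        for t in tracks
        for p in t.points
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Counts removed by each stage of the land → speed → class pipeline."""

    n_input: int
    n_removed_land: int = 0
    n_removed_speed: int = 0
    n_removed_class: int = 0

    @property
    def n_output(self) -> int:
        return (
            self.n_input
            - self.n_removed_land
            - self.n_removed_speed
            - self.n_removed_class
        )

    def fractions(self) -> dict[str, float]:
        if self.n_input == 0:
            return {"land": 0.0, "speed": 0.0, "class": 0.0}
        return {
            "land": self.n_removed_land / self.n_input,
            "speed": self.n_removed_speed / self.n_input,
            "class": self.n_removed_class / self.n_input,
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema": "mixedstock.filter_report/1",
            "n_input": self.n_input,
            "n_removed_land": self.n_removed_land,
            "n_removed_speed": self.n_removed_speed,
            "n_removed_class": self.n_removed_class,
            "n_output": self.n_output,
            "fractions": self.fractions(),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def filter_land(track: Track, mask: LandMask) -> tuple[Track, list[TrackPoint]]:
    """Drop points whose nearest mask cell is land."""
    kept, removed = [], []
    for p in track.points:
        (removed if mask.is_land(p.lon, p.lat) else kept).append(p)
    return Track(track.track_id, kept), removed


def filter_speed(
    track: Track, vmax_kmh: float = 10.0
) -> tuple[Track, list[TrackPoint]]:
    """Forward pass against the last retained point.

    The first point is always retained.  A point is removed when its
    great-circle speed from the last retained point is strictly above
    ``vmax_kmh``, or when it duplicates the last retained timestamp (zero
    time gap) — the later record is dropped.
    """
    if not track.points:
        return track, []
    kept = [track.points[0]]
    removed = []
    for p in track.points[1:]:
        last = kept[-1]
        dt_h = (p.timestamp - last.timestamp).total_seconds() / 3600.0
        if dt_h <= 0.0:
            removed.append(p)
            continue
        speed = haversine_km((last.lon, last.lat), (p.lon, p.lat)) / dt_h
        if speed > vmax_kmh:
            removed.append(p)
        else:
            kept.append(p)
    return Track(track.track_id, kept), removed


def filter_class(
    track: Track, excluded: set[str] = frozenset({"Z"})
) -> tuple[Track, list[TrackPoint]]:
    """Drop points whose Argos location class is in ``excluded``."""
    kept = [p for p in track.points if p.loc_class not in excluded]
    removed = [p for p in track.points if p.loc_class in excluded]
    return Track(track.track_id, kept), removed


def apply_filter_pipeline(
    track: Track,
    mask: LandMask | None = None,
    vmax_kmh: float = 10.0,
    excluded_classes: set[str] = frozenset({"Z"}),
) -> tuple[Track, FilterReport]:
    """Land → speed → class, with a :class:`FilterReport` against n_input."""
    report = FilterReport(n_input=len(track))
    if mask is not None:
        track, removed = filter_land(track, mask)
        report.n_removed_land = len(removed)
    track, removed = filter_speed(track, vmax_kmh)
    report.n_removed_speed = len(removed)
    track, removed = filter_class(track, excluded_classes)
    report.n_removed_class = len(removed)
    return track, report


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class TrackSummary:
    track_id: str
    n_loc: int
    duration_days: float
    distance_km: float
    speed_mean_kmh: float | None
    speed_sd_kmh: float | None


def summarize_track(track: Track) -> TrackSummary:
    """Locations, duration, great-circle path length, and segment speeds."""
    n = len(track)
    if n == 0:
        raise ValueError("cannot summarize an empty track")
    if n == 1:
        return TrackSummary(track.track_id, 1, 0.0, 0.0, None, None)
    duration_s = (
        track.points[-1].timestamp - track.points[0].timestamp
    ).total_seconds()
    dists, speeds = [], []
    for a, b in zip(track.points, track.points[1:]):
        d = haversine_km((a.lon, a.lat), (b.lon, b.lat))
        dists.append(d)
        dt_h = (b.timestamp - a.timestamp).total_seconds() / 3600.0
        if dt_h > 0:
            speeds.append(d / dt_h)
    mean = float(np.mean(speeds)) if speeds else None
    sd = float(np.std(speeds, ddof=1)) if len(speeds) > 1 else None
    return TrackSummary(
        track.track_id,
        n,
        duration_s / 86_400.0,
        float(np.sum(dists)),
        mean,
        sd,
    )


def summarize_cohort(
    summaries: Sequence[TrackSummary] | pd.DataFrame,
    extra_columns: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Column-wise mean and sample (n−1) SD across tracks.

    Accepts either :class:`TrackSummary` objects or a DataFrame of numeric
    per-track columns (e.g. a published summary table); ``extra_columns``
    (indexed like the summaries) are appended before aggregating.  Returns
    a two-row frame indexed ``mean`` / ``sd``.
    """
    if isinstance(summaries, pd.DataFrame):
        df = summaries.copy()
    else:
        df = pd.DataFrame(
            {
                "track_id": [s.track_id for s in summaries],
                "n_loc": [s.n_loc for s in summaries],
                "duration_days": [s.duration_days for s in summaries],
                "distance_km": [s.distance_km for s in summaries],
                "speed_mean_kmh": [s.speed_mean_kmh for s in summaries],
                "speed_sd_kmh": [s.speed_sd_kmh for s in summaries],
            }
        )
    if extra_columns is not None:
        df = pd.concat([df.reset_index(drop=True), extra_columns.reset_index(drop=True)], axis=1)
    num = df.select_dtypes(include=[np.number])
    if num.empty or len(df) == 0:
        raise ValueError("no numeric columns or no tracks to summarize")
    if len(df) < 2:
        raise ValueError("cohort SD needs at least 2 tracks")
    return pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)}).T
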