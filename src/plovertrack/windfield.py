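"""Gridded pressure-level winds: I/O, interpolation and wind support.

Wind grids are 4-D (time, level, latitude, longitude) eastward (u) and
northward (v) components in m/s, the layout of an ERA5-style reanalysis
extract. Levels are pressure surfaces in mbar, with the integer code 0
standing for the 10 m above-ground "surface" wind; the analysis vocabulary
is {surface, 1000, 850, 700, 500} mbar (roughly 10 m, 100 m, 1500 m,
3000 m and 5500 m asl).

Wind support along a track bearing θ is computed from the components,

    support = u · sin θ + v · cos θ   [m/s],

which is algebraically the classical v_w · cos(α) with v_w the wind speed
and α the angle between the track direction and the direction the wind
blows toward. Positive support is tailwind, negative is headwind. Working
in components sidesteps the meteorological direction-from / direction-to
convention trap.

Interpolation is trilinear — bilinear in latitude/longitude and linear in
time — applied to u and v independently; levels are never interpolated
between. Queries outside the grid hull raise rather than extrapolate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .errors import DomainError, FormatError, OutOfDomainError
from .geodesy import Segment
from .trackio import Track

logger = logging.getLogger(__name__)


def _axis_trend(vals) -> int:
    """+1 strictly increasing, -1 strictly decreasing, 0 otherwise."""
    if len(vals) < 2:
        return 1
    d = np.diff(vals)
    zero = d.dtype.type(0)
    if np.all(d > zero):
        return 1
    if np.all(d < zero):
        return -1
    return 0


#: level code for the 10 m above-ground wind
SURFACE = 0
LEVELS = (SURFACE, 1000, 850, 700, 500)
LEVEL_NAMES = {SURFACE: "PLsurface", 1000: "PL1000", 850: "PL850", 700: "PL700", 500: "PL500"}

#: accepted axis / variable aliases in input NetCDF files
AXIS_ALIASES = {
    "time": ("time", "valid_time"),
    "level": ("level", "pressure_level", "plev"),
    "latitude": ("latitude", "lat"),
    "longitude": ("longitude", "lon"),
}
VAR_ALIASES = {"u": ("u", "u10", "u_component"), "v": ("v", "v10", "v_component")}


@dataclass
class WindGrid:
    """A validated 4-D u/v wind field on strictly monotone axes."""

    ds: xr.Dataset

    def __post_init__(self) -> None:
        for name in ("time", "level", "latitude", "longitude"):
            if name not in self.ds.dims:
                raise FormatError(f"wind grid lacks axis {name!r}")
            if _axis_trend(self.ds[name].values) != 1:
                raise FormatError(f"axis {name!r} is not strictly increasing")
        for var in ("u", "v"):
            if var not in self.ds:
                raise FormatError(f"wind grid lacks variable {var!r}")
            if tuple(self.ds[var].dims) != ("time", "level", "latitude", "longitude"):
                raise FormatError(f"variable {var!r} must be (time, level, latitude, longitude)")
        if self.ds["u"].shape != self.ds["v"].shape:
            raise FormatError("u and v shapes differ")
        if bool(self.ds["u"].isnull().any()) or bool(self.ds["v"].isnull().any()):
            raise FormatError("missing values inside the declared domain")

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.ds["time"].values)

    @property
    def levels(self) -> np.ndarray:
        return self.ds["level"].values

    @property
    def lats(self) -> np.ndarray:
        return self.ds["latitude"].values

    @property
    def lons(self) -> np.ndarray:
        return self.ds["longitude"].values

    def to_netcdf(self, path: str | Path) -> None:
        enc = {
            "time": {"dtype": "float64", "units": "hours since 1970-01-01"},
            "level": {"dtype": "int32"},
            "latitude": {"dtype": "float64"},
            "longitude": {"dtype": "float64"},
            "u": {"dtype": "float64"},
            "v": {"dtype": "float64"},
        }
        self.ds.to_netcdf(path, engine="scipy", encoding=enc)

    @classmethod
    def from_arrays(cls, times, levels, lats, lons, u, v) -> "WindGrid":
        levels = np.asarray(levels, dtype=int)
        order = np.argsort(levels)
        levels = levels[order]
        u = np.asarray(u, dtype=float)[:, order]
        v = np.asarray(v, dtype=float)[:, order]
        ds = xr.Dataset(
            {
                "u": (("time", "level", "latitude", "longitude"), np.asarray(u, dtype=float)),
                "v": (("time", "level", "latitude", "longitude"), np.asarray(v, dtype=float)),
            },
            coords={
                "time": pd.DatetimeIndex(times),
                "level": np.asarray(levels, dtype=int),
                "latitude": np.asarray(lats, dtype=float),
                "longitude": np.asarray(lons, dtype=float),
            },
        )
        ds["u"].attrs["units"] = ds["v"].attrs["units"] = "m s-1"
        return cls(ds)


def read_wind_grid(
    path: str | Path,
    axis_names: Mapping[str, str] | None = None,
    var_names: Mapping[str, str] | None = None,
) -> WindGrid:
    """Open a NetCDF wind file, normalising axis order and names.

    Axes found under common CF aliases (remappable through ``axis_names`` /
    ``var_names``) are renamed to the canonical time/level/latitude/longitude
    and reordered ascending; descending input axes are flipped with the data
    permuted consistently.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"wind file not found: {path}")
    ds = xr.open_dataset(path, engine="scipy")

    rename: dict[str, str] = {}
    for canon, aliases in AXIS_ALIASES.items():
        cand = [axis_names[canon]] if axis_names and canon in axis_names else list(aliases)
        found = next((c for c in cand if c in ds.dims or c in ds.coords), None)
        if found is None:
            raise FormatError(f"no {canon} axis among {cand} in {path.name}")
        if found != canon:
            rename[found] = canon
    for canon, aliases in VAR_ALIASES.items():
        cand = [var_names[canon]] if var_names and canon in var_names else list(aliases)
        found = next((c for c in cand if c in ds.data_vars), None)
        if found is None:
            raise FormatError(f"no {canon} wind variable among {cand} in {path.name}")
        if found != canon:
            rename[found] = canon
    ds = ds.rename(rename)

    for name in ("time", "level", "latitude", "longitude"):
        if _axis_trend(ds[name].values) == -1:
            ds = ds.isel({name: slice(None, None, -1)})
    ds = ds[["u", "v"]].transpose("time", "level", "latitude", "longitude")
    ds["level"] = ds["level"].values.astype(int)
    return WindGrid(ds)


@dataclass(frozen=True)
class WindSample:
    """Interpolated wind at one point: components plus derived polar form."""

    u: float
    v: float
    level: int

    @property
    def speed(self) -> float:
        return float(np.hypot(self.u, self.v))

    @property
    def direction_to_deg(self) -> float:
        """Direction the wind blows toward, degrees clockwise from north."""
        return float(np.degrees(np.arctan2(self.u, self.v)) % 360.0)


def interp_wind_vec(grid: WindGrid, lats, lons, times, level: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised trilinear interpolation of u and v at one pressure level.

    Returns NaN for points outside the spatial/temporal hull; callers decide
    whether that is an error or a skip.
    """
    if level not in grid.levels:
        raise OutOfDomainError(f"level {level} not in grid levels {list(grid.levels)}")
    sel = grid.ds.sel(level=level)
    pts = {
        "time": xr.DataArray(pd.DatetimeIndex(np.atleast_1d(times)), dims="pt"),
        "latitude": xr.DataArray(np.atleast_1d(np.asarray(lats, dtype=float)), dims="pt"),
        "longitude": xr.DataArray(np.atleast_1d(np.asarray(lons, dtype=float)), dims="pt"),
    }
    out = sel.interp(**pts, method="linear", kwargs={"fill_value": np.nan})
    return out["u"].values, out["v"].values


def interp_wind(grid: WindGrid, lat: float, lon: float, time, level: int) -> WindSample:
    """Trilinearly interpolated wind sample at a single space-time point."""
    u, v = interp_wind_vec(grid, [lat], [lon], [pd.Timestamp(time)], level)
    if np.isnan(u[0]) or np.isnan(v[0]):
        raise OutOfDomainError(
            f"query ({lat}, {lon}, {time}) outside wind-grid hull; extrapolation refused"
        )
    return WindSample(float(u[0]), float(v[0]), level)


def wind_support(sample: WindSample, track_bearing_deg: float) -> float:
    """Wind component along the track bearing, m/s (tailwind positive)."""
    theta = np.radians(track_bearing_deg)
    return float(sample.u * np.sin(theta) + sample.v * np.cos(theta))


def wind_support_uv(u, v, track_bearing_deg):
    """Array form of :func:`wind_support` on raw components."""
    theta = np.radians(np.asarray(track_bearing_deg, dtype=float))
    return np.asarray(u) * np.sin(theta) + np.asarray(v) * np.cos(theta)


@dataclass(frozen=True)
class SupportRecord:
    """Wind support for one track segment at one pressure level."""

    segment: Segment
    level: int
    u: float
    v: float
    support: float


def annotate_track(
    segments: Sequence[Segment],
    grid: WindGrid,
    levels: Iterable[int] = LEVELS,
) -> list[SupportRecord]:
    """One SupportRecord per segment x level, sampled at segment midpoints.

    The sampling point of a segment is its great-circle midpoint at the
    mid-time. Segments whose midpoint falls outside the grid hull are
    skipped with a logged count.
    """
    segments = list(segments)
    if not segments:
        return []
    mids = [s.midpoint for s in segments]
    lats = np.array([m[0] for m in mids])
    lons = np.array([m[1] for m in mids])
    times = pd.DatetimeIndex([s.mid_time for s in segments])
    records: list[SupportRecord] = []
    skipped = 0
    for level in levels:
        u, v = interp_wind_vec(grid, lats, lons, times, level)
        for seg, uu, vv in zip(segments, u, v):
            if np.isnan(uu) or np.isnan(vv):
                skipped += 1
                continue
            records.append(
                SupportRecord(
                    seg, level, float(uu), float(vv),
                    float(wind_support_uv(uu, vv, seg.bearing_deg)),
                )
            )
    if skipped:
        logger.info("annotate_track: %d segment-level samples outside grid hull, skipped", skipped)
    return records


def support_table(records: list[SupportRecord]) -> pd.DataFrame:
    """Tidy frame of support records for CSV export."""
    return pd.DataFrame(
        {
            "start_time": [r.segment.start.timestamp for r in records],
            "end_time": [r.segment.end.timestamp for r in records],
            "mid_lat": [r.segment.midpoint[0] for r in records],
            "mid_lon": [r.segment.midpoint[1] for r in records],
            "bearing_deg": [r.segment.bearing_deg for r in records],
            "ground_speed_kmh": [r.segment.ground_speed_kmh for r in records],
            "level": [r.level for r in records],
            "u_ms": [r.u for r in records],
            "v_ms": [r.v for r in records],
            "support_ms": [r.support for r in records],
        }
    )


def _path_midpoints(path: Sequence[tuple[float, float]]):
    """Midpoints and bearings of the legs of a lat/lon polyline."""
    from .geodesy import gc_point_fraction, initial_bearing

    mids, bearings = [], []
    for (la1, lo1), (la2, lo2) in zip(path, path[1:]):
        if (la1, lo1) == (la2, lo2):
            continue
        mids.append(gc_point_fraction(la1, lo1, la2, lo2, 0.5))
        bearings.append(initial_bearing(la1, lo1, la2, lo2))
    if not mids:
        raise DomainError("path has no non-degenerate legs")
    return np.array(mids), np.array(bearings)


def wind_climatology(
    grids: Mapping[int, WindGrid],
    path: Sequence[tuple[float, float]],
    window: tuple[str, str],
    levels: Iterable[int] = LEVELS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-year mean +/- SD of wind support along a path, plus overlaps.

    ``grids`` maps a year to that year's wind grid; ``window`` is a
    ("MM-DD", "MM-DD") calendar window applied within each year. For every
    grid time inside the window, support is evaluated at the midpoint of
    each path leg against that leg's bearing; the distribution is summarised
    per year and level. The second frame reports, per level and year pair,
    whether the mean +/- SD intervals overlap. Years whose grid does not
    cover the path/window are flagged absent (covered = False).
    """
    mids, bearings = _path_midpoints(path)
    rows = []
    for year, grid in sorted(grids.items()):
        t0 = pd.Timestamp(f"{year}-{window[0]}")
        t1 = pd.Timestamp(f"{year}-{window[1]}")
        times = grid.times[(grid.times >= t0) & (grid.times <= t1)]
        for level in levels:
            supports = []
            if len(times):
                for t in times:
                    u, v = interp_wind_vec(
                        grid, mids[:, 0], mids[:, 1], np.repeat(t, len(mids)), level
                    )
                    s = wind_support_uv(u, v, bearings)
                    supports.extend(s[~np.isnan(s)].tolist())
            covered = len(supports) > 0
            rows.append(
                {
                    "year": year,
                    "level": level,
                    "mean_support_ms": float(np.mean(supports)) if covered else np.nan,
                    "sd_support_ms": float(np.std(supports, ddof=1)) if len(supports) > 1 else (0.0 if covered else np.nan),
                    "n": len(supports),
                    "covered": covered,
                }
            )
    summary = pd.DataFrame(rows)

    overlaps = []
    for level in levels:
        sub = summary[(summary["level"] == level) & summary["covered"]]
        for i, a in sub.iterrows():
            for j, b in sub.iterrows():
                if a["year"] >= b["year"]:
                    continue
                lo = max(a["mean_support_ms"] - a["sd_support_ms"], b["mean_support_ms"] - b["sd_support_ms"])
                hi = min(a["mean_support_ms"] + a["sd_support_ms"], b["mean_support_ms"] + b["sd_support_ms"])
                overlaps.append(
                    {"level": level, "year_a": int(a["year"]), "year_b": int(b["year"]), "overlap": bool(lo <= hi)}
                )
    return summary, pd.DataFrame(overlaps, columns=["level", "year_a", "year_b", "overlap"])


DEFAULT_BBOX = (12.0, 52.0, 81.0, 116.0)  # lat_min, lat_max, lon_min, lon_max


def export_wind_vectors(
    grid: WindGrid,
    bbox: tuple[float, float, float, float] = DEFAULT_BBOX,
    time=None,
    level: int = 850,
    stride: int = 1,
) -> pd.DataFrame:
    """Subsampled (lat, lon, u, v) table for external quiver plotting."""
    lat_min, lat_max, lon_min, lon_max = bbox
    if time is None:
        time = grid.times[0]
    sel = grid.ds.sel(level=level).interp(time=pd.Timestamp(time))
    sel = sel.sel(latitude=slice(lat_min, lat_max), longitude=slice(lon_min, lon_max))
    if sel.sizes["latitude"] == 0 or sel.sizes["longitude"] == 0:
        raise DomainError("bounding box does not intersect the wind grid")
    sel = sel.isel(latitude=slice(None, None, stride), longitude=slice(None, None, stride))
    df = sel[["u", "v"]].to_dataframe().reset_index()
    return df.rename(columns={"latitude": "lat", "longitude": "lon"})[["lat", "lon", "u", "v"]]
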