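"""Reading, validation and filtering of Argos satellite fixes.

Conventions fixed here and relied on by every other module:

* coordinates are WGS84 decimal degrees, longitude normalised to
  (-180, 180];
* timestamps are UTC at second resolution, carried tz-naive (zone-aware
  input is converted to UTC and stripped);
* Argos location classes come from the closed vocabulary
  ``3, 2, 1, 0, A, B, Z`` with quality decreasing left to right.

Classes 3-1 carry stated accuracy bands (within 250 m, 250-500 m and
500-1500 m respectively); 0/A/B are less accurate and only useful while a
bird is in directed flight; Z fixes are invalid and always discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .errors import ConfigurationError, DomainError, EmptyTrackError

logger = logging.getLogger(__name__)

LOC_CLASSES: tuple[str, ...] = ("3", "2", "1", "0", "A", "B", "Z")
#: quality rank, lower = better fix
CLASS_RANK: dict[str, int] = {c: i for i, c in enumerate(LOC_CLASSES)}
#: classes trusted while the bird is stationary (mapping / stopover analysis)
STATIONARY_CLASSES = frozenset({"3", "2", "1"})
#: classes accepted while the bird is moving (flight timing and speeds)
MOVING_CLASSES = frozenset({"3", "2", "1", "0", "A", "B"})

FilterMode = Literal["stationary", "moving"]


def normalize_lon(lon: float) -> float:
    """Wrap a longitude into (-180, 180]."""
    wrapped = ((float(lon) + 180.0) % 360.0) - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


@dataclass(frozen=True)
class Fix:
    """One timestamped Argos position with a location class."""

    animal_id: str
    timestamp: pd.Timestamp
    lat: float
    lon: float
    loc_class: str

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise DomainError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 < self.lon <= 180.0:
            raise DomainError(f"longitude {self.lon} outside (-180, 180]")
        if self.loc_class not in LOC_CLASSES:
            raise DomainError(f"unknown Argos class {self.loc_class!r}")


@dataclass
class Track:
    """An animal's fixes in strictly increasing time order."""

    animal_id: str
    fixes: list[Fix] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.fixes)

    def __iter__(self):
        return iter(self.fixes)

    @property
    def start(self) -> pd.Timestamp:
        return self.fixes[0].timestamp

    @property
    def end(self) -> pd.Timestamp:
        return self.fixes[-1].timestamp

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": [f.animal_id for f in self.fixes],
                "timestamp": [f.timestamp for f in self.fixes],
                "lat": [f.lat for f in self.fixes],
                "lon": [f.lon for f in self.fixes],
                "loc_class": [f.loc_class for f in self.fixes],
            }
        )


@dataclass(frozen=True)
class ColumnMap:
    """Input/output column names; defaults follow the Movebank dialect."""

    timestamp: str = "timestamp"
    lat: str = "location-lat"
    lon: str = "location-long"
    loc_class: str = "argos:lc"
    animal_id: str = "individual-local-identifier"

    def required(self) -> tuple[str, ...]:
        return (self.timestamp, self.lat, self.lon, self.loc_class)


DEFAULT_COLUMNS = ColumnMap()


def _parse_rows(df: pd.DataFrame, columns: ColumnMap, animal: str) -> tuple[list[Fix], int]:
    """Validate raw rows; return clean fixes plus a rejected-row count."""
    ts = pd.to_datetime(df[columns.timestamp], errors="coerce", utc=True, format="mixed").dt.tz_localize(None)
    lat = pd.to_numeric(df[columns.lat], errors="coerce")
    lon = pd.to_numeric(df[columns.lon], errors="coerce")
    lc = df[columns.loc_class].astype(str).str.strip().str.upper()

    fixes: list[Fix] = []
    rejected = 0
    for t, la, lo, c in zip(ts, lat, lon, lc):
        if pd.isna(t) or pd.isna(la) or pd.isna(lo):
            rejected += 1
            continue
        if not (-90.0 <= la <= 90.0) or c not in LOC_CLASSES:
            rejected += 1
            continue
        fixes.append(Fix(animal, t.floor("s"), float(la), normalize_lon(lo), c))
    return fixes, rejected


def _dedupe(fixes: list[Fix]) -> list[Fix]:
    """Resolve duplicate timestamps: keep the best class, tie -> first seen."""
    best: dict[pd.Timestamp, Fix] = {}
    for f in fixes:
        held = best.get(f.timestamp)
        if held is None or CLASS_RANK[f.loc_class] < CLASS_RANK[held.loc_class]:
            best[f.timestamp] = f
    return [best[t] for t in sorted(best)]


def read_track(
    path: str | Path,
    columns: ColumnMap = DEFAULT_COLUMNS,
    animal_id: str | None = None,
) -> Track:
    """Read one animal's track from a delimited text file.

    Rows with unparseable coordinates/timestamps, out-of-bounds latitudes or
    unknown location classes are dropped and counted in the log. Fixes are
    returned sorted by time with duplicate timestamps resolved in favour of
    the better location class.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in columns.required() if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing mandatory column(s) {missing} in {path}")

    if columns.animal_id in df.columns:
        ids = df[columns.animal_id].dropna().unique().tolist()
        if animal_id is not None:
            df = df[df[columns.animal_id] == animal_id]
            animal = animal_id
        elif len(ids) == 1:
            animal = str(ids[0])
        elif len(ids) > 1:
            raise ConfigurationError(
                f"{path} holds several animals {ids}; pass animal_id to choose one"
            )
        else:
            animal = "unknown"
    else:
        animal = animal_id or "unknown"

    fixes, rejected = _parse_rows(df, columns, animal)
    if rejected:
        logger.info("read_track(%s): rejected %d of %d rows", path.name, rejected, len(df))
    fixes = _dedupe(fixes)
    if not fixes:
        raise EmptyTrackError(f"no valid fixes in {path}")
    return Track(animal, fixes)


def write_track(track: Track, path: str | Path, columns: ColumnMap = DEFAULT_COLUMNS) -> None:
    """Write a track as Movebank-dialect CSV (inverse of :func:`read_track`)."""
    df = pd.DataFrame(
        {
            columns.timestamp: [f.timestamp.strftime("%Y-%m-%d %H:%M:%S") for f in track.fixes],
            columns.lat: [repr(f.lat) for f in track.fixes],
            columns.lon: [repr(f.lon) for f in track.fixes],
            columns.loc_class: [f.loc_class for f in track.fixes],
            columns.animal_id: [f.animal_id for f in track.fixes],
        }
    )
    df.to_csv(path, index=False)


def filter_by_class(track: Track, mode: FilterMode) -> Track:
    """Keep fixes whose class is trusted for the given behavioural mode.

    ``stationary`` keeps classes {3, 2, 1}; ``moving`` additionally keeps
    {0, A, B}. Class Z is always dropped.
    """
    if mode == "stationary":
        keep = STATIONARY_CLASSES
    elif mode == "moving":
        keep = MOVING_CLASSES
    else:
        raise ConfigurationError(f"unknown filter mode {mode!r}")
    return Track(track.animal_id, [f for f in track.fixes if f.loc_class in keep])


def from_dataframe(df: pd.DataFrame, animal_id: str = "unknown") -> Track:
    """Build a Track from a tidy frame with timestamp/lat/lon/loc_class columns."""
    def _naive(t) -> pd.Timestamp:
        t = pd.Timestamp(t)
        return t.tz_convert("UTC").tz_localize(None) if t.tzinfo is not None else t

    fixes = [
        Fix(
            str(row.get("animal_id", animal_id)),
            _naive(row["timestamp"]),
            float(row["lat"]),
            normalize_lon(row["lon"]),
            str(row["loc_class"]),
        )
        for _, row in df.iterrows()
    ]
    fixes.sort(key=lambda f: f.timestamp)
    return Track(animal_id, fixes)
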