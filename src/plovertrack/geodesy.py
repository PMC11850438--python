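"""Spherical-earth geodesy: distance, bearing, speed and interpolation.

All distances are great-circle (haversine) on a sphere of authalic radius
``R = 6371.0088 km``; at the leg lengths involved in shorebird migration
(hundreds to thousands of km) this agrees with ellipsoidal geodesics to a
few km, well under Argos position error. Bearings are initial forward
azimuths, degrees clockwise from true north in [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, UndefinedBearingError
from .trackio import Fix, Track

EARTH_RADIUS_KM = 6371.0088


def _check_bounds(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 360.0):
        raise DomainError("coordinates outside valid ranges")


def great_circle_km(lat1, lon1, lat2, lon2):
    """Haversine great-circle distance in km; accepts scalars or arrays."""
    _check_bounds(lat1, lon1)
    _check_bounds(lat2, lon2)
    p1, l1, p2, l2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    a = np.sin((p2 - p1) / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d.item() if np.isscalar(lat1) or np.ndim(d) == 0 else d


def initial_bearing(lat1, lon1, lat2, lon2) -> float:
    """Forward azimuth from point 1 to point 2, degrees in [0, 360)."""
    _check_bounds(lat1, lon1)
    _check_bounds(lat2, lon2)
    if lat1 == lat2 and (lon1 - lon2) % 360.0 == 0.0:
        raise UndefinedBearingError("bearing undefined between identical points")
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    y = np.sin(l2 - l1) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(l2 - l1)
    return float(np.degrees(np.arctan2(y, x)) % 360.0)


@dataclass(frozen=True)
class Segment:
    """A directed leg between two fixes with derived motion quantities."""

    start: Fix
    end: Fix
    distance_km: float
    elapsed_h: float
    ground_speed_kmh: float
    bearing_deg: float

    @property
    def mid_time(self) -> pd.Timestamp:
        return self.start.timestamp + (self.end.timestamp - self.start.timestamp) / 2

    @property
    def midpoint(self) -> tuple[float, float]:
        return gc_point_fraction(
            self.start.lat, self.start.lon, self.end.lat, self.end.lon, 0.5
        )


def segment_speed(a: Fix, b: Fix) -> Segment:
    """Build the Segment a->b; ground speed = distance / elapsed time."""
    elapsed_h = (b.timestamp - a.timestamp).total_seconds() / 3600.0
    if elapsed_h <= 0.0:
        raise DomainError("segment requires strictly increasing timestamps")
    d = great_circle_km(a.lat, a.lon, b.lat, b.lon)
    if d == 0.0:
        bearing = 0.0  # speed is 0; bearing is arbitrary for a null displacement
    else:
        bearing = initial_bearing(a.lat, a.lon, b.lat, b.lon)
    return Segment(a, b, d, elapsed_h, d / elapsed_h, bearing)


def track_segments(track: Track) -> list[Segment]:
    """Segments between consecutive fixes of a track."""
    return [segment_speed(a, b) for a, b in zip(track.fixes, track.fixes[1:])]


def cumulative_distance(track: Track) -> float:
    """Sum of consecutive great-circle legs — the minimum flight distance."""
    if len(track) < 2:
        raise DomainError("cumulative distance needs at least 2 fixes")
    f = track.fixes
    lats = np.array([x.lat for x in f])
    lons = np.array([x.lon for x in f])
    return float(np.sum(great_circle_km(lats[:-1], lons[:-1], lats[1:], lons[1:])))


def _to_unit(lat: float, lon: float) -> np.ndarray:
    p, l = np.radians([lat, lon])
    return np.array([np.cos(p) * np.cos(l), np.cos(p) * np.sin(l), np.sin(p)])


def _from_unit(v: np.ndarray) -> tuple[float, float]:
    lat = float(np.degrees(np.arcsin(np.clip(v[2], -1.0, 1.0))))
    lon = float(np.degrees(np.arctan2(v[1], v[0])))
    return lat, 180.0 if lon == -180.0 else lon


def gc_point_fraction(lat1: float, lon1: float, lat2: float, lon2: float, f: float) -> tuple[float, float]:
    """Point a fraction ``f`` of the way along the great circle 1 -> 2 (slerp)."""
    u1, u2 = _to_unit(lat1, lon1), _to_unit(lat2, lon2)
    omega = np.arccos(np.clip(np.dot(u1, u2), -1.0, 1.0))
    if omega < 1e-12:
        return lat1, lon1
    v = (np.sin((1.0 - f) * omega) * u1 + np.sin(f * omega) * u2) / np.sin(omega)
    return _from_unit(v / np.linalg.norm(v))


def interpolate_track(track: Track, step_minutes: float) -> Track:
    """Insert constant-speed great-circle points at a regular time step.

    Within each consecutive pair of fixes the position is advanced along
    the great circle in proportion to elapsed time (ground speed and
    direction assumed constant over the leg). The time grid sits on whole
    multiples of ``step_minutes`` from the leg start; original fixes are
    preserved exactly.
    """
    if len(track) < 2:
        raise DomainError("interpolation needs at least 2 fixes")
    if step_minutes <= 0:
        raise DomainError("step must be positive")
    step = pd.Timedelta(minutes=step_minutes)
    out: list[Fix] = []
    for a, b in zip(track.fixes, track.fixes[1:]):
        out.append(a)
        span = b.timestamp - a.timestamp
        k = 1
        while k * step < span:
            frac = (k * step) / span
            lat, lon = gc_point_fraction(a.lat, a.lon, b.lat, b.lon, frac)
            out.append(Fix(a.animal_id, (a.timestamp + k * step).floor("s"), lat, lon, a.loc_class))
            k += 1
    out.append(track.fixes[-1])
    return Track(track.animal_id, out)
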