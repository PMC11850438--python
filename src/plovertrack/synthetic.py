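"""Synthetic Argos tracks and analytic wind grids with known ground truth.

The track generator emulates the sampling regime of a solar-powered 5-g
satellite transmitter: a duty cycle of 10 h transmitting / 48 h charging,
fixes only inside on-windows, and isotropic Gaussian position jitter whose
scale depends on the Argos location class. Default jitter SDs: class 3
0.25 km, class 2 0.5 km, class 1 1.5 km (the stated accuracy bands of the
good classes), and conventional magnitudes 5 / 10 / 20 km for classes
0 / A / B. Fixes taken while the bird is settled draw mostly good classes;
fixes in flight draw mostly poor ones, matching how class quality degrades
on a moving platform.

A plan is a list of waypoints, each with an arrival and departure instant:
the bird sits at a waypoint between the two, then flies the great circle
to the next waypoint at the constant speed required to arrive on time
(a plan whose required leg speed exceeds the plan airspeed ceiling is
rejected as infeasible). Waypoints with positive residence are the planted
stopovers and form the ground truth against which detection is scored.

Wind grids are built from analytic fields (uniform, affine, or sinusoidal
per level) and returned together with a closed-form model, so that
interpolation and wind-support code can be checked against exact values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import PlanError
from .geodesy import gc_point_fraction, great_circle_km, initial_bearing
from .trackio import Fix, Track
from .windfield import LEVELS, WindGrid, wind_support_uv

#: default per-class position jitter, km
DEFAULT_ERROR_SD_KM = {"3": 0.25, "2": 0.5, "1": 1.5, "0": 5.0, "A": 10.0, "B": 20.0}
#: class mix while settled at a site
DEFAULT_STATIONARY_MIX = {"3": 0.35, "2": 0.35, "1": 0.20, "0": 0.06, "A": 0.03, "B": 0.01}
#: class mix while in directed flight
DEFAULT_MOVING_MIX = {"0": 0.40, "A": 0.30, "B": 0.20, "1": 0.06, "2": 0.03, "3": 0.01}

KM_PER_DEG_LAT = 111.32


@dataclass(frozen=True)
class Waypoint:
    lat: float
    lon: float
    arrival: pd.Timestamp
    departure: pd.Timestamp
    label: str = ""

    @property
    def stay_days(self) -> float:
        return (self.departure - self.arrival).total_seconds() / 86400.0


@dataclass
class TrackPlan:
    waypoints: list[Waypoint]
    airspeed_kmh: float = 60.0
    duty_on_h: float = 10.0
    duty_off_h: float = 48.0
    fix_interval_h: float = 1.0
    error_sd_km: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ERROR_SD_KM))
    stationary_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_STATIONARY_MIX))
    moving_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MOVING_MIX))
    #: emit an exact (class 3) fix at every waypoint arrival/departure instant
    anchor_waypoints: bool = True
    #: duty-cycle phase origin; defaults to the first waypoint's arrival
    duty_anchor: pd.Timestamp | None = None
    animal_id: str = "SYN"
    seed: int = 0

    def validate(self) -> None:
        w = self.waypoints
        if len(w) < 2:
            raise PlanError("plan needs at least 2 waypoints")
        for a in w:
            if a.departure < a.arrival:
                raise PlanError(f"waypoint {a.label or a.lat, a.lon}: departure before arrival")
        for a, b in zip(w, w[1:]):
            if b.arrival <= a.departure:
                raise PlanError("waypoint times must increase between consecutive waypoints")
            dist = great_circle_km(a.lat, a.lon, b.lat, b.lon)
            hours = (b.arrival - a.departure).total_seconds() / 3600.0
            if dist / hours > self.airspeed_kmh:
                raise PlanError(
                    f"leg {a.label}->{b.label} needs {dist / hours:.1f} km/h "
                    f"> airspeed {self.airspeed_kmh} km/h"
                )
        for mix in (self.stationary_mix, self.moving_mix):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise PlanError("class mix probabilities must sum to 1")


@dataclass
class TrackTruth:
    """Ground truth recorded alongside a generated track."""

    stopovers: list[Waypoint]
    waypoints: list[Waypoint]


def _position(plan: TrackPlan, t: pd.Timestamp) -> tuple[float, float, bool]:
    """(lat, lon, is_stationary) of the planned trajectory at time t."""
    w = plan.waypoints
    if t <= w[0].departure:
        return w[0].lat, w[0].lon, True
    for a, b in zip(w, w[1:]):
        if t <= b.arrival:
            frac = (t - a.departure) / (b.arrival - a.departure)
            lat, lon = gc_point_fraction(a.lat, a.lon, b.lat, b.lon, float(frac))
            return lat, lon, False
        if t <= b.departure:
            return b.lat, b.lon, True
    return w[-1].lat, w[-1].lon, True


def _in_on_window(plan: TrackPlan, t: pd.Timestamp, anchor: pd.Timestamp) -> bool:
    cycle = plan.duty_on_h + plan.duty_off_h
    phase = ((t - anchor).total_seconds() / 3600.0) % cycle
    return phase < plan.duty_on_h


def gen_track(plan: TrackPlan) -> tuple[Track, TrackTruth]:
    """Realise a plan as a duty-cycled, jittered Argos-like track.

    Deterministic given the plan (including its seed). Ground truth lists
    the planted stopovers: waypoints with positive residence.
    """
    plan.validate()
    rng = np.random.default_rng(plan.seed)
    w = plan.waypoints
    anchor = plan.duty_anchor if plan.duty_anchor is not None else w[0].arrival
    start, end = w[0].arrival, w[-1].departure

    times: list[pd.Timestamp] = []
    step = pd.Timedelta(hours=plan.fix_interval_h)
    t = start
    while t <= end:
        if _in_on_window(plan, t, anchor):
            times.append(t)
        t = t + step
    if plan.anchor_waypoints:
        for wp in w:
            times.extend([wp.arrival, wp.departure])
    times = sorted(set(times))

    s_classes = list(plan.stationary_mix)
    s_probs = np.array([plan.stationary_mix[c] for c in s_classes])
    m_classes = list(plan.moving_mix)
    m_probs = np.array([plan.moving_mix[c] for c in m_classes])
    anchor_times = {wp.arrival for wp in w} | {wp.departure for wp in w} if plan.anchor_waypoints else set()

    fixes: list[Fix] = []
    for t in times:
        lat, lon, stationary = _position(plan, t)
        if t in anchor_times:
            cls = "3"
        elif stationary:
            cls = s_classes[rng.choice(len(s_classes), p=s_probs)]
        else:
            cls = m_classes[rng.choice(len(m_classes), p=m_probs)]
        sd = plan.error_sd_km.get(cls, 0.0)
        if sd > 0.0:
            dlat = rng.normal(0.0, sd) / KM_PER_DEG_LAT
            dlon = rng.normal(0.0, sd) / (KM_PER_DEG_LAT * max(np.cos(np.radians(lat)), 0.05))
        else:
            dlat = dlon = 0.0
        fixes.append(
            Fix(plan.animal_id, t.floor("s"), float(np.clip(lat + dlat, -90, 90)), float(lon + dlon), cls)
        )
    truth = TrackTruth(
        stopovers=[wp for wp in w[1:-1] if wp.stay_days > 0.0],
        waypoints=list(w),
    )
    return Track(plan.animal_id, fixes), truth


def random_migration_plan(
    seed: int,
    n_stopovers: int = 3,
    stay_days_range: tuple[float, float] = (5.0, 9.0),
    leg_km_range: tuple[float, float] = (400.0, 800.0),
    start: tuple[float, float] = (5.0, 100.0),
    start_time: str | pd.Timestamp = "2018-04-01 00:00",
) -> TrackPlan:
    """A random northward plan with planted stopovers for recovery studies.

    Stopovers last 5-9 days (the transmitter schedule guarantees at least
    two on-windows inside any stay of 5+ days) and consecutive sites are
    400-800 km apart, comfortably beyond the 150 km clustering radius. The
    duty-cycle phase is randomised through the start time.
    """
    rng = np.random.default_rng(seed)
    t = pd.Timestamp(start_time) + pd.Timedelta(hours=float(rng.uniform(0, 58)))
    lat, lon = start
    wps = [Waypoint(lat, lon, t, t, label="origin")]
    airspeed = 60.0
    for i in range(n_stopovers + 1):
        dist = float(rng.uniform(*leg_km_range))
        bearing = float(rng.uniform(-30.0, 30.0)) % 360.0  # broadly northward
        dlat = dist * np.cos(np.radians(bearing)) / KM_PER_DEG_LAT
        dlon = dist * np.sin(np.radians(bearing)) / (KM_PER_DEG_LAT * np.cos(np.radians(lat)))
        lat, lon = lat + dlat, lon + dlon
        arrive = wps[-1].departure + pd.Timedelta(hours=dist / airspeed * 1.5)
        if i < n_stopovers:
            stay = pd.Timedelta(days=float(rng.uniform(*stay_days_range)))
            wps.append(Waypoint(lat, lon, arrive, arrive + stay, label=f"stop{i + 1}"))
        else:
            wps.append(Waypoint(lat, lon, arrive, arrive, label="terminus"))
    return TrackPlan(waypoints=wps, airspeed_kmh=airspeed, seed=seed)


# ---------------------------------------------------------------------------
# analytic wind fields


@dataclass
class WindPlan:
    """Recipe for an analytic wind grid.

    ``field_kind`` selects the functional form; ``params`` maps each level
    to that form's parameters:

    * ``uniform``:    {"u": u0, "v": v0}
    * ``linear``:     {"u0", "u_lat", "u_lon", "u_t", "v0", "v_lat",
                       "v_lon", "v_t"} — affine in lat, lon and time
                       (hours since the first grid time)
    * ``sinusoidal``: {"amp_u", "amp_v", "wavelength_deg", "phase"} —
                      u = amp_u·sin(2π·lat/λ + φ), v = amp_v·cos(2π·lon/λ + φ)
    """

    field_kind: str
    params: Mapping[int, Mapping[str, float]]
    lat_range: tuple[float, float] = (0.0, 60.0)
    lon_range: tuple[float, float] = (80.0, 130.0)
    dlat: float = 2.0
    dlon: float = 2.0
    times: Sequence[pd.Timestamp] | None = None
    time_start: str | pd.Timestamp = "2018-09-01 00:00"
    time_hours: float = 96.0
    time_step_h: float = 6.0
    levels: Sequence[int] = LEVELS
    seed: int = 0


@dataclass
class WindFieldModel:
    """Closed-form u/v field used to oracle-check interpolation and support."""

    plan: WindPlan
    t0: pd.Timestamp

    def uv(self, lat, lon, time, level: int) -> tuple[np.ndarray, np.ndarray]:
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        th = (pd.DatetimeIndex(np.atleast_1d(time)) - self.t0).total_seconds() / 3600.0
        th = np.asarray(th, dtype=float)
        p = self.plan.params[level]
        if self.plan.field_kind == "uniform":
            u = np.full(np.broadcast(lat, lon, th).shape, float(p["u"]))
            v = np.full_like(u, float(p["v"]))
        elif self.plan.field_kind == "linear":
            u = p.get("u0", 0.0) + p.get("u_lat", 0.0) * lat + p.get("u_lon", 0.0) * lon + p.get("u_t", 0.0) * th
            v = p.get("v0", 0.0) + p.get("v_lat", 0.0) * lat + p.get("v_lon", 0.0) * lon + p.get("v_t", 0.0) * th
            u, v = np.broadcast_arrays(u, v)
            u, v = np.asarray(u, dtype=float), np.asarray(v, dtype=float)
        elif self.plan.field_kind == "sinusoidal":
            lam = p.get("wavelength_deg", 30.0)
            ph = p.get("phase", 0.0)
            u = p.get("amp_u", 0.0) * np.sin(2 * np.pi * lat / lam + ph) + np.zeros_like(th)
            v = p.get("amp_v", 0.0) * np.cos(2 * np.pi * lon / lam + ph) + np.zeros_like(th)
        else:
            raise PlanError(f"unknown field kind {self.plan.field_kind!r}")
        return u, v

    def support(self, lat, lon, time, level: int, bearing_deg) -> np.ndarray:
        u, v = self.uv(lat, lon, time, level)
        return wind_support_uv(u, v, bearing_deg)


def gen_wind_grid(plan: WindPlan) -> tuple[WindGrid, WindFieldModel]:
    """Materialise an analytic wind plan on a regular grid."""
    if plan.times is not None:
        times = pd.DatetimeIndex(plan.times)
    else:
        t0 = pd.Timestamp(plan.time_start)
        times = pd.DatetimeIndex(
            [t0 + pd.Timedelta(hours=h) for h in np.arange(0.0, plan.time_hours + 1e-9, plan.time_step_h)]
        )
    lats = np.arange(plan.lat_range[0], plan.lat_range[1] + 1e-9, plan.dlat)
    lons = np.arange(plan.lon_range[0], plan.lon_range[1] + 1e-9, plan.dlon)
    model = WindFieldModel(plan, times[0])

    LA, LO = np.meshgrid(lats, lons, indexing="ij")
    u = np.empty((len(times), len(plan.levels), len(lats), len(lons)))
    v = np.empty_like(u)
    for it, t in enumerate(times):
        for il, level in enumerate(plan.levels):
            uu, vv = model.uv(LA.ravel(), LO.ravel(), np.repeat(t, LA.size), level)
            u[it, il] = np.asarray(uu).reshape(LA.shape)
            v[it, il] = np.asarray(vv).reshape(LA.shape)
    grid = WindGrid.from_arrays(times, list(plan.levels), lats, lons, u, v)
    return grid, model


def gen_coupled(
    path: Sequence[tuple[float, float]],
    model: WindFieldModel,
    level: int,
    slope: float = 1.0,
    noise_sd_kmh: float = 5.0,
    airspeed_kmh: float = 60.0,
    start_time: str | pd.Timestamp = "2018-09-01 12:00",
    seed: int = 0,
    animal_id: str = "CPL",
) -> tuple[Track, np.ndarray]:
    """Track whose ground speeds are airspeed + slope·support + noise.

    Support (converted to km/h) is taken from the closed-form field at each
    leg's great-circle midpoint; segment times are then laid out so that
    distance / elapsed time reproduces the constructed speed exactly.
    Speeds that would fall below 1 km/h are truncated there and logged.
    Returns the track and the per-segment support values (km/h).
    """
    rng = np.random.default_rng(seed)
    t = pd.Timestamp(start_time)
    fixes = [Fix(animal_id, t, path[0][0], path[0][1], "3")]
    supports = []
    truncated = 0
    for (la1, lo1), (la2, lo2) in zip(path, path[1:]):
        dist = great_circle_km(la1, lo1, la2, lo2)
        brg = initial_bearing(la1, lo1, la2, lo2)
        mid = gc_point_fraction(la1, lo1, la2, lo2, 0.5)
        sup_kmh = float(model.support(mid[0], mid[1], t, level, brg)[0]) * 3.6
        speed = airspeed_kmh + slope * sup_kmh + rng.normal(0.0, noise_sd_kmh)
        if speed < 1.0:
            speed = 1.0
            truncated += 1
        t = t + pd.Timedelta(hours=dist / speed)
        fixes.append(Fix(animal_id, t, la2, lo2, "3"))
        supports.append(sup_kmh)
    if truncated:
        import logging

        logging.getLogger(__name__).info("gen_coupled: %d speeds truncated at 1 km/h", truncated)
    return Track(animal_id, fixes), np.array(supports)
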