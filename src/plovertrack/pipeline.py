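"""End-to-end orchestration: track -> stopovers -> winds -> speed models.

`run_all` composes the stage modules in the order of the field workflow:
class filtering, stopover segmentation and phase classification on the
stationary-quality fixes; speed computation and apparent-speed exclusion on
the moving-quality fixes; midpoint wind annotation at the analysis pressure
levels; and per-period ordinary least squares of ground speed on wind
support. Everything is deterministic given the inputs and configuration,
and all products are written as CSV/JSON alongside a run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference, synthetic
from .errors import DomainError
from .geodesy import gc_point_fraction, great_circle_km, track_segments
from .segmentation import (
    DEFAULT_BREEDING_MIN_DAYS,
    DEFAULT_MIN_DAYS,
    DEFAULT_RADIUS_KM,
    Phase,
    PhaseKind,
    assign_phases,
    detect_stopovers,
    stopover_table,
)
from .speedstats import (
    DEFAULT_MIN_PERIOD_N,
    DEFAULT_MIN_SPEED_KMH,
    build_period_datasets,
    filter_speed,
    period_models,
)
from .trackio import Track, filter_by_class, read_track
from .windfield import (
    LEVELS,
    WindGrid,
    annotate_track,
    interp_wind_vec,
    read_wind_grid,
    support_table,
    wind_support_uv,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and thresholds for a full pipeline run."""

    track_csv: str | None = None  # None -> synthetic B3-like reconstruction
    wind_nc: str | None = None  # None -> bundled analytic wind field
    radius_km: float = DEFAULT_RADIUS_KM
    min_days: float = DEFAULT_MIN_DAYS
    min_speed_kmh: float = DEFAULT_MIN_SPEED_KMH
    breeding_min_days: float = DEFAULT_BREEDING_MIN_DAYS
    min_period_n: int = DEFAULT_MIN_PERIOD_N
    levels: Sequence[int] = LEVELS
    interp_step_min: float = 30.0
    support_units: str = "m/s"
    seed: int = 0
    outdir: str = "results"

    def validate(self) -> None:
        for name in ("radius_km", "min_days", "min_speed_kmh", "breeding_min_days"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        unknown = [lv for lv in self.levels if lv not in LEVELS]
        if unknown:
            raise DomainError(f"levels {unknown} outside the analysis vocabulary {LEVELS}")


def default_wind_plan(track: Track, levels: Sequence[int]) -> synthetic.WindPlan:
    """An analytic wind field spanning a track's space-time footprint.

    Zonal flow strengthening and veering with altitude — a crude but
    serviceable stand-in for midlatitude conditions when no reanalysis
    extract is supplied.
    """
    lats = [f.lat for f in track.fixes]
    lons = [f.lon for f in track.fixes]
    params = {
        lv: {
            "u0": u0,
            "u_lat": 0.05,
            "v0": v0,
            "v_lon": 0.01,
        }
        for lv, u0, v0 in zip(LEVELS, (1.0, 2.0, 4.0, 7.0, 11.0), (0.5, 0.5, 0.0, -0.5, -1.0))
        if lv in levels
    }
    start = track.start.floor("D") - pd.Timedelta(days=1)
    hours = (track.end - start).total_seconds() / 3600.0 + 48.0
    return synthetic.WindPlan(
        field_kind="linear",
        params=params,
        lat_range=(min(lats) - 3.0, max(lats) + 3.0),
        lon_range=(min(lons) - 3.0, max(lons) + 3.0),
        dlat=2.0,
        dlon=2.0,
        time_start=start,
        time_hours=hours,
        time_step_h=24.0,
        levels=tuple(levels),
    )


def phase_summary(phases: Sequence[Phase]) -> dict:
    """Durations (whole days) of the migration phases, plus the composite
    southward period that includes the post-breeding staging."""
    out: dict[str, int | None] = {}
    by_kind = {p.kind: p for p in phases if p.kind is not PhaseKind.WINTERING}
    for kind in (PhaseKind.NORTHWARD, PhaseKind.BREEDING, PhaseKind.POST_BREEDING, PhaseKind.SOUTHWARD):
        p = by_kind.get(kind)
        out[kind.value.lower() + "_days"] = p.duration_days if p else None
    pb, sw = by_kind.get(PhaseKind.POST_BREEDING), by_kind.get(PhaseKind.SOUTHWARD)
    out["southward_total_days"] = (
        (pb.duration_days if pb else 0) + sw.duration_days if sw else None
    )
    return out


def run_all(config: RunConfig) -> dict:
    """Run every stage; write tables under ``config.outdir``; return results.

    The returned mapping carries the in-memory products: ``track``,
    ``stopovers``, ``phases``, ``stopover_table``, ``supports`` (DataFrame),
    ``models`` (DataFrame) and ``summary`` (dict).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.track_csv:
        track = read_track(config.track_csv)
    else:
        track, _ = synthetic.gen_track(reference.b3_plan(seed=config.seed))

    stationary = filter_by_class(track, "stationary")
    stopovers = detect_stopovers(stationary, config.radius_km, config.min_days)
    phases = assign_phases(stopovers, stationary, config.breeding_min_days)
    table = stopover_table(stopovers, phases)
    table.to_csv(outdir / "stopovers.csv", index=False)

    if config.wind_nc:
        grid = read_wind_grid(config.wind_nc)
    else:
        grid, _ = synthetic.gen_wind_grid(default_wind_plan(track, config.levels))

    moving = filter_by_class(track, "moving")
    segments = filter_speed(track_segments(moving), config.min_speed_kmh)
    records = annotate_track(segments, grid, config.levels)
    supports = support_table(records)
    supports.to_csv(outdir / "supports.csv", index=False)

    datasets = build_period_datasets(records, phases, config.min_speed_kmh)
    models = period_models(datasets, config.levels, config.support_units, config.min_period_n)
    models.to_csv(outdir / "models.csv", index=False)

    summary = {
        "config": {
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "n_fixes": len(track),
        "n_fixes_stationary": len(stationary),
        "n_fixes_moving": len(moving),
        "n_flight_segments": len(segments),
        "n_stopovers": len(table[table["migration_status"].str.contains("Stopover|Breeding")]),
        "phases": phase_summary(phases),
        "period_n": {k.value: d.n for k, d in datasets.items()},
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    logger.info("run_all: wrote stopovers/supports/models/summary to %s", outdir)
    return {
        "track": track,
        "stopovers": stopovers,
        "phases": phases,
        "stopover_table": table,
        "supports": supports,
        "models": models,
        "summary": summary,
    }


def densify_route(route: Sequence[tuple[float, float]], step_km: float = 100.0) -> list[tuple[float, float]]:
    """Great-circle densification of a waypoint route at roughly step_km."""
    if len(route) < 2:
        raise DomainError("a route needs at least 2 points")
    pts: list[tuple[float, float]] = [tuple(route[0])]
    for (la1, lo1), (la2, lo2) in zip(route, route[1:]):
        dist = great_circle_km(la1, lo1, la2, lo2)
        n = max(int(np.ceil(dist / step_km)), 1)
        for k in range(1, n + 1):
            pts.append(gc_point_fraction(la1, lo1, la2, lo2, k / n))
    return pts


def compare_routes(
    routes: Mapping[str, Sequence[tuple[float, float]]],
    grid: WindGrid,
    window: tuple[str | pd.Timestamp, str | pd.Timestamp],
    levels: Sequence[int] = LEVELS,
    step_km: float = 100.0,
) -> pd.DataFrame:
    """Mean +/- SD wind support along each route over a time window.

    Each route is densified along the great circle; support is evaluated at
    every leg midpoint against the leg bearing, at every grid time inside
    the window. Routes that fall outside the grid hull are flagged
    (covered = False) rather than fatal.
    """
    from .windfield import _path_midpoints

    t0, t1 = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    times = grid.times[(grid.times >= t0) & (grid.times <= t1)]
    rows = []
    for name, route in routes.items():
        path = densify_route(route, step_km)
        mids, bearings = _path_midpoints(path)
        for level in levels:
            supports: list[float] = []
            for t in times:
                u, v = interp_wind_vec(grid, mids[:, 0], mids[:, 1], np.repeat(t, len(mids)), level)
                s = wind_support_uv(u, v, bearings)
                supports.extend(s[~np.isnan(s)].tolist())
            covered = len(supports) > 0
            if not covered:
                logger.warning("compare_routes: route %r outside grid hull at level %s", name, level)
            rows.append(
                {
                    "route": name,
                    "level": level,
                    "mean_support_ms": float(np.mean(supports)) if covered else np.nan,
                    "sd_support_ms": float(np.std(supports, ddof=1)) if len(supports) > 1 else (0.0 if covered else np.nan),
                    "n": len(supports),
                    "covered": covered,
                }
            )
    return pd.DataFrame(rows)
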