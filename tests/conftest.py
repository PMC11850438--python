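"""Shared fixtures: reconstruction track, analytic wind grids, small plans."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from plovertrack import reference, synthetic
from plovertrack.segmentation import assign_phases, detect_stopovers
from plovertrack.synthetic import TrackPlan, Waypoint
from plovertrack.trackio import filter_by_class


@pytest.fixture(scope="session")
def b3():
    """Generated reconstruction of the 2018 migration timetable plus its
    detected stopovers and phases (stationary-class fixes only)."""
    track, truth = synthetic.gen_track(reference.b3_plan(seed=1))
    stationary = filter_by_class(track, "stationary")
    stops = detect_stopovers(stationary)
    phases = assign_phases(stops, stationary)
    return {"track": track, "truth": truth, "stationary": stationary, "stopovers": stops, "phases": phases}


def planted_753_plan() -> TrackPlan:
    """Three stopovers of 7, 3 and 5 days, 400+ km apart, duty phase fixed
    so the 3-day stay intersects two transmission windows."""
    t0 = pd.Timestamp("2018-04-01 00:00")

    def at(h: float) -> pd.Timestamp:
        return t0 + pd.Timedelta(hours=h)

    # leg distances ~700/600/800/500 km northward; the 3-day site arrives
    # 228 h after the duty anchor (228 mod 58 = 54, inside the detectable
    # phase band [44, 58) u [0, 10))
    wps = [
        Waypoint(10.0, 100.0, at(0), at(0), "origin"),
        Waypoint(16.3, 100.0, at(14), at(14 + 168), "stop1"),  # 7 days
        Waypoint(21.7, 100.0, at(228), at(228 + 72), "stop2"),  # 3 days
        Waypoint(28.9, 100.0, at(316), at(316 + 120), "stop3"),  # 5 days
        Waypoint(33.4, 100.0, at(448), at(448), "terminus"),
    ]
    return TrackPlan(waypoints=wps, airspeed_kmh=60.0, anchor_waypoints=False, seed=7)


@pytest.fixture()
def plan_753() -> TrackPlan:
    return planted_753_plan()


@pytest.fixture(scope="session")
def uniform_grid():
    """u = 8 m/s westerly, v = 0, at all five analysis levels."""
    plan = synthetic.WindPlan(
        field_kind="uniform",
        params={lv: {"u": 8.0, "v": 0.0} for lv in (0, 1000, 850, 700, 500)},
        lat_range=(-5.0, 60.0),
        lon_range=(80.0, 130.0),
        time_start="2018-09-01 00:00",
        time_hours=240.0,
        time_step_h=24.0,
    )
    return synthetic.gen_wind_grid(plan)


@pytest.fixture(scope="session")
def linear_grid():
    """Field affine in lat, lon and time — reproduced exactly by trilinear
    interpolation, hence an exactness fixture."""
    plan = synthetic.WindPlan(
        field_kind="linear",
        params={
            850: {"u0": 2.0, "u_lat": 0.3, "u_lon": -0.1, "u_t": 0.05, "v0": -1.0, "v_lat": 0.1, "v_lon": 0.02, "v_t": -0.01},
            700: {"u0": 5.0, "u_lat": 0.1, "v0": 0.5, "v_lon": -0.04},
        },
        lat_range=(0.0, 60.0),
        lon_range=(80.0, 130.0),
        dlat=5.0,
        dlon=5.0,
        time_start="2018-09-01 00:00",
        time_hours=48.0,
        time_step_h=12.0,
        levels=(850, 700),
    )
    return synthetic.gen_wind_grid(plan)
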