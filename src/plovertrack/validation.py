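"""Self-validation experiments run against planted synthetic ground truth.

These are the package's calibration checks: stopover-detection sensitivity
under the transmitter duty cycle, slope recovery and confidence-interval
coverage of the ground-speed ~ wind-support regression, the algebraic
equivalence of the two wind-support formulations, and agreement between the
haversine distance and an independent spherical-law-of-cosines form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodesy import EARTH_RADIUS_KM, great_circle_km, track_segments
from .segmentation import detect_stopovers
from .speedstats import ols_fit
from .synthetic import WindPlan, gen_coupled, gen_track, gen_wind_grid, random_migration_plan
from .trackio import filter_by_class
from .windfield import WindSample, wind_support


@dataclass
class RecoveryResult:
    n_planted: int
    n_recovered: int
    n_spurious: int

    @property
    def sensitivity_pct(self) -> float:
        return 100.0 * self.n_recovered / self.n_planted


def stopover_recovery(
    n_seeds: int = 50,
    seed0: int = 0,
    match_km: float = 50.0,
) -> RecoveryResult:
    """Detect planted stopovers on seeded duty-cycled tracks.

    Each seeded track plants stopovers of 5-9 days, 400-800 km apart, under
    the 10 h / 48 h duty cycle with class-dependent jitter and no anchor
    fixes. A planted site counts as recovered when a detected centroid lies
    within ``match_km``; a detected site matching no plant is spurious.
    """
    planted = recovered = spurious = 0
    for k in range(n_seeds):
        plan = random_migration_plan(seed0 + k)
        plan.anchor_waypoints = False
        track, truth = gen_track(plan)
        found = detect_stopovers(filter_by_class(track, "stationary"))
        planted += len(truth.stopovers)
        matched = set()
        for s in found:
            d = [
                great_circle_km(s.centroid_lat, s.centroid_lon, w.lat, w.lon)
                for w in truth.stopovers
            ]
            j = int(np.argmin(d)) if d else -1
            if j >= 0 and d[j] <= match_km:
                matched.add(j)
            else:
                spurious += 1
        recovered += len(matched)
    return RecoveryResult(planted, recovered, spurious)


@dataclass
class CoverageResult:
    n_seeds: int
    n_covered: int
    mean_slope: float

    @property
    def coverage_pct(self) -> float:
        return 100.0 * self.n_covered / self.n_seeds


def _coupling_field():
    plan = WindPlan(
        field_kind="linear",
        params={850: {"u0": 2.0, "u_lat": 0.2, "v0": 1.0, "v_lon": -0.05}},
        lat_range=(0.0, 80.0),
        lon_range=(70.0, 150.0),
        levels=(850,),
        time_hours=4800.0,
        time_step_h=1200.0,
    )
    return gen_wind_grid(plan)


def slope_ci_coverage(
    n_seeds: int = 100,
    n_segments: int = 50,
    true_slope: float = 1.0,
    noise_sd_kmh: float = 5.0,
    seed0: int = 0,
) -> CoverageResult:
    """Fraction of seeds whose 95% CI covers the planted coupling slope.

    Ground speed is constructed as airspeed + slope·support + N(0, noise)
    on a meandering path through an affine wind field; the regression is
    refit per seed on the realised segment speeds.
    """
    _, model = _coupling_field()
    covered = 0
    slopes = []
    for k in range(n_seeds):
        rng = np.random.default_rng(seed0 + 10_000 + k)
        lat, lon = 10.0, 100.0
        path = [(lat, lon)]
        for _ in range(n_segments):
            b = rng.uniform(-60.0, 60.0)
            lat += 1.2 * np.cos(np.radians(b))
            lon += 1.2 * np.sin(np.radians(b))
            path.append((lat, lon))
        track, support_kmh = gen_coupled(
            path, model, 850, slope=true_slope, noise_sd_kmh=noise_sd_kmh, seed=seed0 + 20_000 + k
        )
        speeds = [s.ground_speed_kmh for s in track_segments(track)]
        fit = ols_fit(support_kmh, speeds)
        lo, hi = fit.ci95()
        covered += int(lo <= true_slope <= hi)
        slopes.append(fit.coefficient)
    return CoverageResult(n_seeds, covered, float(np.mean(slopes)))


def support_identity_max_error(n: int = 10_000, seed: int = 0) -> float:
    """Max |u·sinθ + v·cosθ − v_w·cos(α)| over random samples and bearings."""
    rng = np.random.default_rng(seed)
    u = rng.uniform(-30.0, 30.0, n)
    v = rng.uniform(-30.0, 30.0, n)
    bearing = rng.uniform(0.0, 360.0, n)
    worst = 0.0
    for uu, vv, bb in zip(u, v, bearing):
        s = WindSample(float(uu), float(vv), 850)
        via_components = wind_support(s, float(bb))
        alpha = np.radians(s.direction_to_deg - bb)
        via_angle = s.speed * np.cos(alpha)
        worst = max(worst, abs(via_components - via_angle))
    return worst


def trilinear_affine_max_error(seed: int = 0, n: int = 500) -> float:
    """Max interpolation error on a field affine in lat, lon and time."""
    from .windfield import interp_wind_vec

    plan = WindPlan(
        field_kind="linear",
        params={850: {"u0": 3.0, "u_lat": 0.25, "u_lon": -0.08, "u_t": 0.04,
                      "v0": -2.0, "v_lat": 0.05, "v_lon": 0.03, "v_t": -0.02}},
        lat_range=(0.0, 60.0), lon_range=(80.0, 130.0), dlat=5.0, dlon=5.0,
        levels=(850,), time_hours=48.0, time_step_h=12.0,
    )
    grid, model = gen_wind_grid(plan)
    rng = np.random.default_rng(seed)
    lats = rng.uniform(0.0, 60.0, n)
    lons = rng.uniform(80.0, 130.0, n)
    times = pd.Timestamp("2018-09-01") + pd.to_timedelta(rng.uniform(0.0, 48.0, n), unit="h")
    u, v = interp_wind_vec(grid, lats, lons, times, 850)
    eu, ev = model.uv(lats, lons, times, 850)
    return float(max(np.max(np.abs(u - eu)), np.max(np.abs(v - ev))))


def haversine_cosine_max_diff(n: int = 10_000, seed: int = 0) -> float:
    """Max |haversine − law of cosines| (km) over random point pairs."""
    rng = np.random.default_rng(seed)
    la1 = rng.uniform(-85.0, 85.0, n)
    la2 = rng.uniform(-85.0, 85.0, n)
    lo1 = rng.uniform(-180.0, 180.0, n)
    lo2 = rng.uniform(-180.0, 180.0, n)
    hav = great_circle_km(la1, lo1, la2, lo2)
    p1, p2 = np.radians(la1), np.radians(la2)
    dl = np.radians(lo2 - lo1)
    cosine = EARTH_RADIUS_KM * np.arccos(
        np.clip(np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl), -1.0, 1.0)
    )
    return float(np.max(np.abs(hav - cosine)))
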