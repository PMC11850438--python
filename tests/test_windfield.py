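"""Wind grids, trilinear interpolation and the wind-support statistic.

The interpolation oracle is an independently coded 8-corner weighted sum;
the support oracle is the speed-times-cosine form v_w cos(alpha).
"""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st

from plovertrack.errors import DomainError, FormatError, OutOfDomainError
from plovertrack.geodesy import segment_speed, interpolate_track, track_segments
from plovertrack.synthetic import WindPlan, gen_wind_grid
from plovertrack.trackio import Fix, Track
from plovertrack.windfield import (
    WindGrid,
    WindSample,
    annotate_track,
    export_wind_vectors,
    interp_wind,
    read_wind_grid,
    wind_climatology,
    wind_support,
    wind_support_uv,
)


def _tiny_grid(u=None, v=None, lats=(10.0, 20.0), lons=(100.0, 110.0)):
    times = pd.DatetimeIndex(["2018-09-01 00:00", "2018-09-01 12:00"])
    levels = [850, 700]
    shape = (2, 2, len(lats), len(lons))
    u = np.arange(np.prod(shape), dtype=float).reshape(shape) if u is None else u
    v = -np.arange(np.prod(shape), dtype=float).reshape(shape) if v is None else v
    return WindGrid.from_arrays(times, levels, lats, lons, u, v)


def test_netcdf_round_trip_is_exact(tmp_path):
    grid = _tiny_grid()
    p = tmp_path / "wind.nc"
    grid.to_netcdf(p)
    back = read_wind_grid(p)
    assert np.array_equal(back.ds["u"].values, grid.ds["u"].values)
    assert np.array_equal(back.ds["v"].values, grid.ds["v"].values)
    assert list(back.levels) == [700, 850]
    assert back.times.equals(grid.times)


def test_descending_latitude_axis_normalised_on_read(tmp_path):
    grid = _tiny_grid()
    flipped = grid.ds.isel(latitude=slice(None, None, -1))
    p = tmp_path / "desc.nc"
    flipped.to_netcdf(
        p, engine="scipy",
        encoding={"time": {"dtype": "float64", "units": "hours since 1970-01-01"}},
    )
    back = read_wind_grid(p)
    assert list(back.lats) == [10.0, 20.0]
    assert np.array_equal(back.ds["u"].values, grid.ds["u"].values)


def test_missing_variable_is_a_format_error(tmp_path):
    grid = _tiny_grid()
    p = tmp_path / "nov.nc"
    grid.ds.drop_vars("v").to_netcdf(
        p, engine="scipy",
        encoding={"time": {"dtype": "float64", "units": "hours since 1970-01-01"}},
    )
    with pytest.raises(FormatError):
        read_wind_grid(p)


def test_interp_reproduces_grid_nodes_and_uniform_fields():
    grid = _tiny_grid()
    s = interp_wind(grid, 20.0, 110.0, "2018-09-01 12:00", 700)
    node = float(grid.ds["u"].sel(time="2018-09-01 12:00", level=700, latitude=20.0, longitude=110.0))
    assert s.u == pytest.approx(node, abs=1e-12)
    plan = WindPlan(
        field_kind="uniform", params={850: {"u": 5.0, "v": 0.0}},
        lat_range=(0, 40), lon_range=(90, 120), levels=(850,),
    )
    ugrid, _ = gen_wind_grid(plan)
    s2 = interp_wind(ugrid, 17.3, 101.9, "2018-09-02 07:00", 850)
    assert (s2.u, s2.v) == (pytest.approx(5.0), pytest.approx(0.0))
    assert s2.speed == pytest.approx(5.0) and s2.direction_to_deg == pytest.approx(90.0)


def _corner_oracle(grid, lat, lon, time, level):
    """Independent trilinear value: explicit 8-corner weight enumeration."""
    da_u = grid.ds["u"].sel(level=level)
    da_v = grid.ds["v"].sel(level=level)
    tvals = grid.times.view("int64").astype(float)
    tq = float(pd.Timestamp(time).value)

    def bracket(vals, q):
        i = int(np.searchsorted(vals, q, side="right") - 1)
        i = min(max(i, 0), len(vals) - 2)
        w = (q - vals[i]) / (vals[i + 1] - vals[i])
        return i, w

    it, wt = bracket(tvals, tq)
    ia, wa = bracket(np.asarray(grid.lats, dtype=float), lat)
    io, wo = bracket(np.asarray(grid.lons, dtype=float), lon)
    out = []
    for da in (da_u, da_v):
        acc = 0.0
        for dt_, ft in ((0, 1 - wt), (1, wt)):
            for da_i, fa in ((0, 1 - wa), (1, wa)):
                for do, fo in ((0, 1 - wo), (1, wo)):
                    acc += ft * fa * fo * float(da.values[it + dt_, ia + da_i, io + do])
        out.append(acc)
    return tuple(out)


def test_trilinear_matches_corner_weight_oracle():
    grid = _tiny_grid()
    rng = np.random.default_rng(99)
    for _ in range(50):
        lat = rng.uniform(10, 20)
        lon = rng.uniform(100, 110)
        t = pd.Timestamp("2018-09-01 00:00") + pd.Timedelta(hours=rng.uniform(0, 12))
        s = interp_wind(grid, lat, lon, t, 850)
        ou, ov = _corner_oracle(grid, lat, lon, t, 850)
        assert s.u == pytest.approx(ou, abs=1e-9)
        assert s.v == pytest.approx(ov, abs=1e-9)


def test_linear_in_lon_field_interpolates_midway():
    lats = (0.0, 10.0)
    lons = (80.0, 90.0)
    shape = (2, 2, 2, 2)
    u = np.broadcast_to(np.array(lons), shape).astype(float)
    v = np.zeros(shape)
    grid = WindGrid.from_arrays(
        pd.DatetimeIndex(["2018-09-01", "2018-09-02"]), [850, 700], lats, lons, u, v
    )
    s = interp_wind(grid, 5.0, 85.0, "2018-09-01 12:00", 850)
    assert s.u == pytest.approx(85.0, abs=1e-12)


def test_out_of_domain_queries_refused():
    grid = _tiny_grid()
    with pytest.raises(OutOfDomainError):
        interp_wind(grid, 50.0, 105.0, "2018-09-01 06:00", 850)
    with pytest.raises(OutOfDomainError):
        interp_wind(grid, 15.0, 105.0, "2018-09-05 00:00", 850)
    with pytest.raises(OutOfDomainError):
        interp_wind(grid, 15.0, 105.0, "2018-09-01 06:00", 500)


def test_wind_support_cardinal_cases():
    s = WindSample(u=10.0, v=0.0, level=850)  # blowing toward 90 deg
    assert wind_support(s, 90.0) == pytest.approx(10.0, abs=1e-12)
    assert wind_support(s, 0.0) == pytest.approx(0.0, abs=1e-12)
    assert wind_support(s, 270.0) == pytest.approx(-10.0, abs=1e-12)


@given(st.floats(-30, 30), st.floats(-30, 30), st.floats(0, 360))
@settings(deadline=None, max_examples=200)
def test_support_bounded_by_speed_and_antisymmetric(u, v, bearing):
    s = WindSample(u=u, v=v, level=850)
    sup = wind_support(s, bearing)
    assert abs(sup) <= s.speed + 1e-9
    assert sup + wind_support(s, bearing + 180.0) == pytest.approx(0.0, abs=1e-9)


def test_interpolation_exact_for_affine_fields(linear_grid):
    grid, model = linear_grid
    rng = np.random.default_rng(5)
    lats = rng.uniform(0, 60, 200)
    lons = rng.uniform(80, 130, 200)
    times = pd.Timestamp("2018-09-01") + pd.to_timedelta(rng.uniform(0, 48, 200), unit="h")
    for level in (850, 700):
        from plovertrack.windfield import interp_wind_vec

        u, v = interp_wind_vec(grid, lats, lons, times, level)
        eu, ev = model.uv(lats, lons, times, level)
        assert np.max(np.abs(u - eu)) < 1e-9
        assert np.max(np.abs(v - ev)) < 1e-9


def _eastbound_track(n=4, lat=5.0):
    t0 = pd.Timestamp("2018-09-02")
    return Track(
        "x", [Fix("x", t0 + pd.Timedelta(hours=6 * i), lat, 95.0 + 2 * i, "3") for i in range(n)]
    )


def test_annotate_uniform_field_equal_support_all_levels(uniform_grid):
    grid, _ = uniform_grid
    segs = track_segments(_eastbound_track(lat=0.0))
    recs = annotate_track(segs, grid)
    assert len(recs) == len(segs) * 5
    for r in recs:
        assert r.support == pytest.approx(8.0, abs=1e-9)
    assert annotate_track(segs, grid, levels=[]) == []


def test_annotate_invariant_to_interpolation_step_on_uniform_field(uniform_grid):
    grid, _ = uniform_grid
    track = _eastbound_track(lat=0.0)
    for step in (30.0, 90.0):
        dense = interpolate_track(track, step)
        recs = annotate_track(track_segments(dense), grid, levels=[850])
        assert np.allclose([r.support for r in recs], 8.0, atol=1e-9)


def test_climatology_identical_years_overlap_and_disjoint_years_do_not():
    path = [(0.0, 95.0), (0.0, 105.0)]  # eastbound along the equator
    mk = lambda u: gen_wind_grid(
        WindPlan(
            field_kind="uniform", params={850: {"u": u, "v": 0.0}},
            lat_range=(-5, 10), lon_range=(90, 110), levels=(850,),
            time_start="2018-09-01", time_hours=72, time_step_h=24,
        )
    )[0]

    same = {2018: mk(10.0), 2019: _shift_year(mk(10.0), 2019)}
    summary, overlap = wind_climatology(same, path, ("09-01", "09-03"), levels=[850])
    assert np.allclose(summary["mean_support_ms"], 10.0, atol=1e-9)
    assert overlap["overlap"].all()

    opposed = {2018: mk(10.0), 2019: _shift_year(mk(-10.0), 2019)}
    summary2, overlap2 = wind_climatology(opposed, path, ("09-01", "09-03"), levels=[850])
    assert not overlap2["overlap"].any()


def _shift_year(grid, year):
    times = pd.DatetimeIndex([t.replace(year=year) for t in grid.times])
    return WindGrid.from_arrays(times, grid.levels, grid.lats, grid.lons, grid.ds["u"].values, grid.ds["v"].values)


def test_climatology_recovers_known_field_statistics():
    plan = WindPlan(
        field_kind="sinusoidal",
        params={850: {"amp_u": 6.0, "amp_v": 0.0, "wavelength_deg": 40.0, "phase": 0.0}},
        lat_range=(-5, 35), lon_range=(90, 110), dlat=0.5, dlon=0.5, levels=(850,),
        time_start="2018-09-01", time_hours=48, time_step_h=24,
    )
    grid, model = gen_wind_grid(plan)
    path = [(0.0, 95.0), (0.0, 96.0), (0.0, 97.0), (0.0, 98.0)]
    summary, _ = wind_climatology({2018: grid}, path, ("09-01", "09-03"), levels=[850])
    # closed form: u(lat=0) = 0 everywhere on this path, support along east = 0
    assert summary["mean_support_ms"].iloc[0] == pytest.approx(0.0, abs=1e-6)
    assert summary.loc[0, "covered"]


def test_climatology_flags_uncovered_year():
    mk = gen_wind_grid(
        WindPlan(
            field_kind="uniform", params={850: {"u": 1.0, "v": 0.0}},
            lat_range=(-5, 10), lon_range=(90, 110), levels=(850,),
            time_start="2018-09-01", time_hours=24, time_step_h=24,
        )
    )[0]
    summary, _ = wind_climatology({2018: mk, 2020: mk}, [(0, 95), (0, 105)], ("09-01", "09-02"), levels=[850])
    row2020 = summary[summary["year"] == 2020].iloc[0]
    assert not row2020["covered"] and np.isnan(row2020["mean_support_ms"])


def test_export_wind_vectors_strides_and_node_values():
    lats = (12.0, 22.0, 32.0, 42.0)
    lons = (85.0, 95.0, 105.0, 115.0)
    shape = (2, 2, 4, 4)
    u = np.arange(np.prod(shape), dtype=float).reshape(shape)
    grid = WindGrid.from_arrays(
        pd.DatetimeIndex(["2018-09-01", "2018-09-02"]), [850, 700], lats, lons, u, np.zeros(shape)
    )
    full = export_wind_vectors(grid, time="2018-09-01", level=850, stride=1)
    assert len(full) == 16
    half = export_wind_vectors(grid, time="2018-09-01", level=850, stride=2)
    assert len(half) == 4
    node = full[(full["lat"] == 22.0) & (full["lon"] == 95.0)].iloc[0]
    s = interp_wind(grid, 22.0, 95.0, "2018-09-01", 850)
    assert node["u"] == pytest.approx(s.u, abs=1e-12)
    with pytest.raises(DomainError):
        export_wind_vectors(grid, bbox=(60.0, 70.0, 0.0, 10.0), time="2018-09-01", level=850)
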