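"""Speed filtering and the ground-speed ~ wind-support regressions."""

import numpy as np
import pandas as pd
import pytest

from plovertrack.errors import DegenerateFitError
from plovertrack.segmentation import Phase, PhaseKind
from plovertrack.speedstats import (
    MS_TO_KMH,
    PeriodDataset,
    build_period_datasets,
    filter_speed,
    ols_fit,
    period_models,
)
from plovertrack.geodesy import Segment, segment_speed
from plovertrack.trackio import Fix


def _segments_with_speeds(speeds):
    t0 = pd.Timestamp("2018-05-01")
    segs = []
    for i, v in enumerate(speeds):
        a = Fix("x", t0 + pd.Timedelta(hours=2 * i), 0.0, float(i), "0")
        b = Fix("x", a.timestamp + pd.Timedelta(hours=1), 0.0, float(i) + v / 111.19, "0")
        segs.append(segment_speed(a, b))
    return segs


def test_speed_filter_keeps_boundary_value():
    segs = _segments_with_speeds([15.0, 25.0, 19.9, 20.0])
    kept = filter_speed(segs)
    assert [round(s.ground_speed_kmh, 1) for s in kept] == [25.0, 20.0]
    assert filter_speed(_segments_with_speeds([5.0, 10.0])) == []


def test_ols_perfect_line_and_degenerate_inputs():
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    fit = ols_fit(x, 2.0 * x)
    assert fit.coefficient == pytest.approx(2.0, abs=1e-12)
    assert fit.r2 == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(DegenerateFitError):
        ols_fit([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(DegenerateFitError):
        ols_fit([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])


def test_ols_matches_hand_normal_equations():
    # small fixture solved independently via the normal equations
    x = np.array([1.0, 2.0, 4.0, 5.0, 7.0, 8.0])
    y = np.array([2.1, 2.9, 5.2, 5.8, 8.1, 8.6])
    n = x.size
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    se = np.sqrt(np.sum(resid**2) / (n - 2) / sxx)
    r2 = np.corrcoef(x, y)[0, 1] ** 2
    from scipy import stats

    p = 2.0 * stats.t.sf(abs(slope / se), n - 2)

    fit = ols_fit(x, y)
    assert fit.coefficient == pytest.approx(slope, abs=1e-6)
    assert fit.intercept == pytest.approx(intercept, abs=1e-6)
    assert fit.se == pytest.approx(se, abs=1e-6)
    assert fit.p == pytest.approx(p, abs=1e-6)
    assert fit.r2 == pytest.approx(r2, abs=1e-6)


def test_ols_null_data_gives_near_zero_slope():
    rng = np.random.default_rng(77)
    x = rng.normal(0.0, 5.0, 1000)
    y = rng.normal(50.0, 5.0, 1000)
    fit = ols_fit(x, y)
    assert abs(fit.coefficient) < 0.1
    assert fit.p > 0.05


def test_ols_scale_equivariance():
    rng = np.random.default_rng(3)
    x = rng.normal(0.0, 3.0, 40)
    y = 50.0 + 0.8 * x + rng.normal(0.0, 2.0, 40)
    base = ols_fit(x, y)
    scaled = ols_fit(10.0 * x, y)
    assert scaled.coefficient == pytest.approx(base.coefficient / 10.0, rel=1e-9)
    assert scaled.r2 == pytest.approx(base.r2, rel=1e-12)
    assert scaled.p == pytest.approx(base.p, rel=1e-9)


def test_ols_p_value_agrees_with_permutation_test():
    rng = np.random.default_rng(21)
    x = rng.normal(0.0, 4.0, 12)
    y = 40.0 + 0.9 * x + rng.normal(0.0, 6.0, 12)
    fit = ols_fit(x, y)

    sxx = np.sum((x - x.mean()) ** 2)
    obs = abs(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    perm_rng = np.random.default_rng(22)
    hits = 0
    n_perm = 10_000
    for _ in range(n_perm):
        yp = perm_rng.permutation(y)
        slope = np.sum((x - x.mean()) * (yp - yp.mean())) / sxx
        hits += abs(slope) >= obs - 1e-15
    p_perm = hits / n_perm
    assert fit.p == pytest.approx(p_perm, abs=0.02)


def _dataset(kind, n, seed, slope=1.0):
    rng = np.random.default_rng(seed)
    ds = PeriodDataset(kind)
    for _ in range(n):
        sup = {lv: float(rng.normal(0.0, 4.0)) for lv in (0, 1000, 850, 700, 500)}
        speed = 55.0 + slope * sup[850] * MS_TO_KMH + float(rng.normal(0, 2.0))
        ds.records.append((speed, sup))
    return ds


def test_period_models_shape_and_small_sample_exclusion(caplog):
    datasets = {
        PhaseKind.NORTHWARD: _dataset(PhaseKind.NORTHWARD, 24, 1),
        PhaseKind.POST_BREEDING: _dataset(PhaseKind.POST_BREEDING, 3, 2),
        PhaseKind.SOUTHWARD: _dataset(PhaseKind.SOUTHWARD, 22, 3),
    }
    table = period_models(datasets)
    assert len(table) == 10  # 2 modelled periods x 5 levels
    assert set(table["period"]) == {"NORTHWARD", "SOUTHWARD"}
    assert set(table["n"]) == {24, 22}
    # the coupled level carries the planted slope (support in m/s -> km/h units)
    row = table[(table["period"] == "NORTHWARD") & (table["level"] == 850)].iloc[0]
    assert row["coefficient"] == pytest.approx(1.0 * MS_TO_KMH, rel=0.15)


def test_period_models_support_unit_conversion():
    datasets = {PhaseKind.NORTHWARD: _dataset(PhaseKind.NORTHWARD, 30, 9)}
    in_ms = period_models(datasets, levels=(850,), support_units="m/s")
    in_kmh = period_models(datasets, levels=(850,), support_units="km/h")
    assert in_kmh["coefficient"].iloc[0] == pytest.approx(
        in_ms["coefficient"].iloc[0] / MS_TO_KMH, rel=1e-9
    )
    assert in_kmh["r2"].iloc[0] == pytest.approx(in_ms["r2"].iloc[0], rel=1e-12)


def test_build_period_datasets_assigns_by_phase_midtime():
    t0 = pd.Timestamp("2018-05-01")
    phases = [
        Phase(PhaseKind.NORTHWARD, t0, t0 + pd.Timedelta(days=10)),
        Phase(PhaseKind.BREEDING, t0 + pd.Timedelta(days=10), t0 + pd.Timedelta(days=20)),
        Phase(PhaseKind.SOUTHWARD, t0 + pd.Timedelta(days=20), t0 + pd.Timedelta(days=30)),
    ]
    from plovertrack.windfield import SupportRecord

    def seg(day, speed):
        a = Fix("x", t0 + pd.Timedelta(days=day), 10.0, 100.0, "0")
        b = Fix("x", a.timestamp + pd.Timedelta(hours=1), 10.0 + speed / 111.19, 100.0, "0")
        return segment_speed(a, b)

    records = [
        SupportRecord(seg(2, 60.0), 850, 5.0, 0.0, 5.0),  # northward
        SupportRecord(seg(15, 60.0), 850, 5.0, 0.0, 5.0),  # breeding -> dropped
        SupportRecord(seg(25, 60.0), 850, 5.0, 0.0, 5.0),  # southward
        SupportRecord(seg(26, 5.0), 850, 5.0, 0.0, 5.0),  # below speed filter
    ]
    out = build_period_datasets(records, phases)
    assert out[PhaseKind.NORTHWARD].n == 1
    assert out[PhaseKind.SOUTHWARD].n == 1
    assert out[PhaseKind.POST_BREEDING].n == 0
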