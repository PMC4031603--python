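import numpy as np
import pytest

from footroll.geometry import REGIONS, StancePhase, build_region_masks, \
    detect_stance_phases
from footroll.pressure_io import PressureRecording, SensorGrid
from footroll.rollover import (CopPath, RegionSeries, UndefinedVelocityError,
                               aggregate_steps, compute_rollover_metrics,
                               cop_mean_velocity, cop_trajectory,
                               metrics_to_tidy, peak_pressure,
                               pressure_time_integral, regional_series,
                               time_to_peak)
from footroll.simulate import RolloverScenario, generate_rollover_recording


def series(values, region="heel"):
    return RegionSeries(region, np.asarray(values, float), True)


def phase_of(values):
    return StancePhase(0, len(values), 100.0)


# ---------------------------------------------------------------------------
# regional series

def hand_masks(grid, assignment):
    """RegionMaskSet with an explicit sensor->region assignment."""
    from footroll.geometry import RegionMaskSet
    labels = np.full(grid.n_sensors, "", dtype=object)
    for region, idx in assignment.items():
        labels[list(idx)] = region
    return RegionMaskSet(labels=labels.astype(str), foot_length=0.3,
                         foot_width=0.1, axis=np.array([0.0, 1.0]),
                         side="left")


def test_single_sensor_region_series_is_identity(grid):
    frames = np.zeros((3, grid.n_sensors))
    frames[:, 0] = [0, 50, 20]
    rec = PressureRecording(grid=grid, sampling_rate=100.0, frames=frames,
                            side="left")
    masks = hand_masks(grid, {"heel": [0]})
    out = {s.region: s for s in regional_series(rec, StancePhase(0, 3, 100.0),
                                                masks)}
    np.testing.assert_array_equal(out["heel"].values, [0, 50, 20])


def test_two_sensor_region_takes_framewise_max(grid):
    frames = np.zeros((2, grid.n_sensors))
    frames[:, 0] = [10, 30]
    frames[:, 1] = [20, 5]
    rec = PressureRecording(grid=grid, sampling_rate=100.0, frames=frames,
                            side="left")
    masks = hand_masks(grid, {"heel": [0, 1]})
    out = {s.region: s for s in regional_series(rec, StancePhase(0, 2, 100.0),
                                                masks)}
    np.testing.assert_array_equal(out["heel"].values, [20, 30])


def test_sensorless_region_yields_inactive_zero_series(grid):
    frames = np.zeros((5, grid.n_sensors))
    frames[:, 0] = 100.0
    rec = PressureRecording(grid=grid, sampling_rate=100.0, frames=frames,
                            side="left")
    masks = hand_masks(grid, {"heel": [0]})
    out = {s.region: s for s in regional_series(rec, StancePhase(0, 5, 100.0),
                                                masks)}
    assert out["heel"].active
    for r in REGIONS:
        if r != "heel":
            assert not out[r].active and np.all(out[r].values == 0)


# ---------------------------------------------------------------------------
# PP / TPP / PTI

@pytest.mark.parametrize("values, expected", [
    ([100, 100, 100], 100.0),
    ([0, 125, 250, 125, 0], 250.0),
    ([0, 0, 0], 0.0),
])
def test_peak_pressure(values, expected):
    assert peak_pressure(series(values)) == expected


@pytest.mark.parametrize("values, expected", [
    (np.arange(11.0), 100.0),           # monotone rise: peak at end
    ([9, 5, 1], 0.0),                   # peak at first frame
    ([0, 1, 2, 7, 4, 5, 7, 3, 2, 1, 0], 30.0),  # tie at 30 % and 60 %
])
def test_time_to_peak(values, expected):
    assert time_to_peak(series(values), phase_of(values)) == \
        pytest.approx(expected)


def test_tpp_matches_first_argmax_scan_oracle():
    rng = np.random.default_rng(5)
    for _ in range(50):
        v = np.round(rng.uniform(0, 10, 21), 0)  # coarse values force ties
        first = next(i for i, x in enumerate(v) if x == v.max())
        assert time_to_peak(series(v), phase_of(v)) == \
            pytest.approx(100.0 * first / 20)


def test_pti_rectangle():
    v = np.full(101, 100.0)  # 1.00 s at 100 Hz
    assert pressure_time_integral(series(v), 100.0) == pytest.approx(100.0)


def test_pti_triangle_closed_form():
    up = np.linspace(0, 200, 26)
    v = np.concatenate([up, up[-2::-1]])  # symmetric, base 0.5 s, peak 200
    assert pressure_time_integral(series(v), 100.0) == pytest.approx(50.0)


def test_pti_zero_series():
    assert pressure_time_integral(series(np.zeros(30)), 100.0) == 0.0


@pytest.mark.parametrize("seed", range(10))
def test_pti_bounded_by_pp_times_duration(seed):
    rng = np.random.default_rng(seed)
    v = rng.uniform(0, 300, rng.integers(5, 80))
    ph = phase_of(v)
    pti = pressure_time_integral(series(v), 100.0)
    assert pti <= peak_pressure(series(v)) * ph.duration + 1e-12
    assert 0 <= time_to_peak(series(v), ph) <= 100


# ---------------------------------------------------------------------------
# COP

def test_single_loaded_sensor_cop_is_fixed(grid):
    frames = np.zeros((10, grid.n_sensors))
    frames[:, 7] = 100.0
    rec = PressureRecording(grid=grid, sampling_rate=100.0, frames=frames,
                            side="left")
    ph = StancePhase(0, 10, 100.0)
    masks = build_region_masks(rec, ph)
    total, _ = cop_trajectory(rec, ph, masks)
    np.testing.assert_allclose(total.points,
                               np.tile(rec.grid.positions[7], (10, 1)))
    assert total.length == 0.0
    assert cop_mean_velocity(total) == 0.0


def test_equal_load_cop_at_midpoint():
    grid = SensorGrid(np.arange(4), np.zeros(4),
                      np.array([0.0, 0.2, 0.05, 0.1]), np.full(4, 1e-4))
    frames = np.zeros((5, 4))
    frames[:, 0] = 80.0
    frames[:, 1] = 80.0
    rec = PressureRecording(grid=grid, sampling_rate=100.0, frames=frames,
                            side="left")
    ph = StancePhase(0, 5, 100.0)
    masks = build_region_masks(rec, ph)
    total, _ = cop_trajectory(rec, ph, masks)
    np.testing.assert_allclose(total.points[:, 1], 0.1)


def test_linear_roll_path_length_matches_displacement(grid):
    # load sweeps linearly heel -> toe: one grid row at a time
    n_rows, n_cols = 30, 10
    frames = np.zeros((n_rows, grid.n_sensors))
    order = np.argsort(grid.y, kind="stable")
    for k in range(n_rows):
        frames[k, order[k * n_cols:(k + 1) * n_cols]] = 150.0
    rec = PressureRecording(grid=grid, sampling_rate=100.0, frames=frames,
                            side="left")
    ph = StancePhase(0, n_rows, 100.0)
    masks = build_region_masks(rec, ph)
    total, _ = cop_trajectory(rec, ph, masks)
    displacement = np.linalg.norm(total.points[-1] - total.points[0])
    assert total.length == pytest.approx(displacement, rel=0.01)


def test_cop_mean_velocity_arithmetic():
    pts = np.column_stack([np.zeros(66), np.linspace(0, 0.20, 66)])
    path = CopPath(pts, np.arange(66), 100.0)
    assert cop_mean_velocity(path) == pytest.approx(0.20 / 0.65, abs=1e-4)


def test_zigzag_velocity_at_least_chord_velocity():
    rng = np.random.default_rng(0)
    pts = np.cumsum(rng.normal(0, 0.01, (40, 2)), axis=0)
    path = CopPath(pts, np.arange(40), 100.0)
    chord = np.linalg.norm(pts[-1] - pts[0]) / (39 / 100.0)
    assert cop_mean_velocity(path) >= chord - 1e-12


def test_velocity_undefined_for_short_path():
    with pytest.raises(UndefinedVelocityError):
        cop_mean_velocity(CopPath(np.zeros((1, 2)), np.array([0]), 100.0))


def test_total_cop_path_length_invariant_under_rigid_motion():
    scenario = RolloverScenario()
    rec, _ = generate_rollover_recording(scenario)
    ph = detect_stance_phases(rec)[0]
    masks = build_region_masks(rec, ph)
    total, _ = cop_trajectory(rec, ph, masks)
    t = np.radians(37.0)
    R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    pos = rec.grid.positions @ R.T + np.array([0.3, -0.1])
    grid2 = SensorGrid(rec.grid.sensor_ids, pos[:, 0], pos[:, 1],
                       rec.grid.area)
    rec2 = PressureRecording(grid=grid2, sampling_rate=100.0,
                             frames=rec.frames, side=rec.side)
    masks2 = build_region_masks(rec2, ph)
    total2, _ = cop_trajectory(rec2, ph, masks2)
    assert total2.length == pytest.approx(total.length, rel=1e-9)


# ---------------------------------------------------------------------------
# aggregation

def _metrics_with_pp(pp_heel):
    scenario = RolloverScenario()
    rec, _ = generate_rollover_recording(scenario)
    ph = detect_stance_phases(rec)[0]
    masks = build_region_masks(rec, ph)
    m = compute_rollover_metrics(rec, ph, masks)
    m.pp["heel"] = pp_heel
    return m


def test_identical_steps_have_zero_sd():
    m = _metrics_with_pp(300.0)
    agg = aggregate_steps([m] * 25)
    assert agg.n_steps == 25
    assert agg.mean.pp["heel"] == pytest.approx(300.0)
    for r in REGIONS:
        assert agg.sd.pp[r] == pytest.approx(0.0, abs=1e-12)
        assert agg.sd.tpp[r] == pytest.approx(0.0, abs=1e-12)


def test_two_step_mean_and_sample_sd():
    agg = aggregate_steps([_metrics_with_pp(200.0), _metrics_with_pp(300.0)])
    assert agg.mean.pp["heel"] == pytest.approx(250.0)
    assert agg.sd.pp["heel"] == pytest.approx(70.7107, abs=1e-3)


def test_single_step_aggregate_is_the_step():
    m = _metrics_with_pp(123.0)
    agg = aggregate_steps([m])
    assert agg.mean.pp["heel"] == 123.0
    assert agg.sd.pp["heel"] == 0.0


def test_tidy_export_has_one_row_per_cell():
    m = _metrics_with_pp(300.0)
    df = metrics_to_tidy([m, m], subject="S1", side="left")
    assert len(df) == 2 * (len(REGIONS) * 4 + 2)
    assert set(df.columns) == {"subject", "side", "step", "region",
                               "variable", "value"}
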