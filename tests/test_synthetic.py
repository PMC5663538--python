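import numpy as np
import pytest

from adchrom import (
    ChannelGeometry,
    FlowCondition,
    GroundTruthTransit,
    Interval,
    RenderConfig,
    SimulationParams,
    fov_positions,
    percent_binding_time,
    render_video,
    simulate_transits,
    transits_to_frame_table,
)
from adchrom.synthetic import BOUND, FREE, _draw_v_roll


def make_geometry(fov_position=12_350.0, fov_length=650.0):
    return ChannelGeometry(
        channel_length_um=fov_position + fov_length,
        fov_length_um=fov_length,
        fov_position_um=fov_position,
    )


class TestSimulateTransits:
    def test_pure_advection_elutes_at_free_flow_time(self, condition):
        """With no capture the whole pulse elutes at L/v_free_flow."""
        geom = make_geometry(fov_position=13_000.0)
        params = SimulationParams(
            n_cells=20, k_on_per_s=0.0, p_start_bound=0.0,
            t_offset_mean_s=0.0, seed=1,
        )
        transits = simulate_transits(params, condition, geom)
        expected = 13_000.0 / 1059.0
        for tr in transits:
            assert tr.t_elution_s == pytest.approx(expected, rel=1e-12)
            assert tr.true_binding_fraction == 0.0

    def test_permanently_bound_cell_rolls_entire_channel(self, condition):
        geom = make_geometry(fov_position=13_000.0)
        params = SimulationParams(
            n_cells=5, k_off_per_s=0.0, p_start_bound=1.0,
            v_roll_mean_um_s=100.0, v_roll_cv=0.0, t_offset_mean_s=0.0, seed=2,
        )
        transits = simulate_transits(params, condition, geom)
        for tr in transits:
            assert tr.t_elution_s == pytest.approx(130.0, rel=1e-12)
            assert tr.true_binding_fraction == 1.0

    def test_offset_limits(self, condition):
        """k_on→0 gives t_offset + L/v_free; k_off→0 (bound) t_offset + L/v_roll."""
        geom = make_geometry(fov_position=13_000.0)
        free = simulate_transits(
            SimulationParams(n_cells=3, k_on_per_s=0.0, p_start_bound=0.0,
                             t_offset_mean_s=30.0, t_offset_cv=0.0, seed=3),
            condition, geom,
        )
        for tr in free:
            assert tr.t_elution_s == pytest.approx(30.0 + 13_000.0 / 1059.0)
        bound = simulate_transits(
            SimulationParams(n_cells=3, k_off_per_s=0.0, p_start_bound=1.0,
                             v_roll_mean_um_s=100.0, v_roll_cv=0.0,
                             t_offset_mean_s=30.0, t_offset_cv=0.0, seed=3),
            condition, geom,
        )
        for tr in bound:
            assert tr.t_elution_s == pytest.approx(160.0)

    def test_stationary_occupancy_matches_discrete_time_oracle(
        self, condition, geometry
    ):
        """At k_on = k_off the mean bound-time fraction sits near the
        stationary occupancy 1/2, agreeing with an independent small-Δt
        discrete-time simulation of the same two-state chain."""
        params = SimulationParams(
            n_cells=1000, k_on_per_s=1.0, k_off_per_s=1.0,
            v_roll_cv=0.0, p_start_bound=0.5, seed=7,
        )
        transits = simulate_transits(params, condition, geometry)
        mean_frac = np.mean([tr.true_binding_fraction for tr in transits])
        assert mean_frac == pytest.approx(0.5, abs=0.02)

        oracle = _discrete_time_bound_fraction(
            n_cells=400, dt=0.002, k_on=1.0, k_off=1.0,
            v_roll=params.v_roll_mean_um_s, v_free=condition.v_free_flow_um_s,
            distance=geometry.fov_position_um, p_start_bound=0.5, seed=17,
        )
        assert mean_frac == pytest.approx(oracle, abs=0.03)

    def test_distance_conservation(self, condition, geometry):
        """Σ duration·velocity over the recorded intervals equals the
        inlet-to-FOV distance for every cell."""
        params = SimulationParams(n_cells=200, seed=5)
        for tr in simulate_transits(params, condition, geometry):
            dist = sum(iv.duration_s * iv.velocity_um_s for iv in tr.intervals)
            assert dist == pytest.approx(geometry.fov_position_um, rel=1e-9)
            assert tr.t_elution_s == pytest.approx(
                tr.t_offset_s + tr.transit_time_s, rel=1e-12
            )
            assert 0.0 <= tr.true_binding_fraction <= 1.0

    def test_mass_balance_identity_on_two_velocity_transits(
        self, condition, geometry, analysis_cfg
    ):
        """For two-velocity transits the mass-balance percent binding time
        recovers the true bound-time fraction to machine precision."""
        params = SimulationParams(n_cells=100, v_roll_cv=0.0, seed=9)
        for tr in simulate_transits(params, condition, geometry):
            value, raw = percent_binding_time(
                condition.v_free_flow_um_s, tr.t_elution_s, tr.t_offset_s,
                geometry.fov_position_um, tr.v_roll_um_s,
            )
            assert raw == pytest.approx(tr.true_binding_fraction, rel=1e-12, abs=1e-12)

    def test_seed_reproducibility(self, condition, geometry):
        params = SimulationParams(n_cells=20, seed=13)
        a = simulate_transits(params, condition, geometry)
        b = simulate_transits(params, condition, geometry)
        assert [tr.t_elution_s for tr in a] == [tr.t_elution_s for tr in b]
        other = simulate_transits(
            SimulationParams(n_cells=20, seed=14), condition, geometry
        )
        assert [tr.t_elution_s for tr in a] != [tr.t_elution_s for tr in other]

    def test_rolling_speed_always_below_free_flow(self, condition, geometry):
        params = SimulationParams(n_cells=300, v_roll_mean_um_s=400.0,
                                  v_roll_cv=1.0, seed=15)
        for tr in simulate_transits(params, condition, geometry):
            assert tr.v_roll_um_s < condition.v_free_flow_um_s

    def test_rolling_speed_redraw_gives_up_eventually(self):
        class AlwaysTooFast:
            def lognormal(self, mu, sigma, size=None):
                return 5000.0

        params = SimulationParams(v_roll_mean_um_s=500.0, v_roll_cv=1.0)
        with pytest.raises(ValueError, match="rolling speed"):
            _draw_v_roll(AlwaysTooFast(), params, 1059.0)

    def test_zero_distance_is_an_error(self, condition):
        geom = ChannelGeometry(channel_length_um=650.0, fov_length_um=650.0)
        assert geom.fov_position_um == 0.0
        with pytest.raises(ValueError, match="zero transit distance"):
            simulate_transits(SimulationParams(n_cells=1, seed=0), condition, geom)

    def test_slow_cells_are_censored(self, condition, geometry):
        params = SimulationParams(
            n_cells=4, k_off_per_s=0.0, p_start_bound=1.0,
            v_roll_mean_um_s=1.0, v_roll_cv=0.0, seed=0,
        )
        transits = simulate_transits(
            params, condition, geometry, acquisition_duration_s=7200.0
        )
        assert all(tr.censored for tr in transits)


def _discrete_time_bound_fraction(
    n_cells, dt, k_on, k_off, v_roll, v_free, distance, p_start_bound, seed
):
    """Independent oracle: Euler-discretized two-state chain advanced until
    each cell covers the distance; returns the mean bound-time fraction."""
    rng = np.random.default_rng(seed)
    bound = rng.random(n_cells) < p_start_bound
    x = np.zeros(n_cells)
    t_total = np.zeros(n_cells)
    t_bound = np.zeros(n_cells)
    done = np.zeros(n_cells, dtype=bool)
    while not done.all():
        alive = ~done
        v = np.where(bound, v_roll, v_free)
        x[alive] += v[alive] * dt
        t_total[alive] += dt
        t_bound[alive] += dt * bound[alive]
        flip = rng.random(n_cells) < np.where(bound, k_off, k_on) * dt
        bound[alive] ^= flip[alive]
        done |= x >= distance
    return float(np.mean(t_bound / t_total))


class TestFovPositions:
    def test_constant_free_flow_step(self, geometry):
        tr = GroundTruthTransit(
            cell_id=0, intervals=[Interval(FREE, 10.0, 1059.0)],
            fov_intervals=[Interval(FREE, 0.6, 1059.0)],
            t_offset_s=0.0, t_elution_s=10.0, true_binding_fraction=0.0,
            v_roll_um_s=100.0,
        )
        t, x, states = fov_positions(tr, geometry, frame_rate_hz=25.0)
        assert np.allclose(np.diff(x), 1059.0 / 25.0)
        assert np.diff(x)[0] == pytest.approx(42.36)
        assert t[0] == pytest.approx(10.0)
        assert all(s == FREE for s in states)

    def test_bound_cell_steps_stay_below_threshold(self, geometry, condition):
        tr = GroundTruthTransit(
            cell_id=0, intervals=[Interval(BOUND, 100.0, 123.5)],
            fov_intervals=[Interval(BOUND, 5.0, 100.0)],
            t_offset_s=0.0, t_elution_s=100.0, true_binding_fraction=1.0,
            v_roll_um_s=100.0,
        )
        _, x, _ = fov_positions(tr, geometry, frame_rate_hz=25.0)
        dt = 1.0 / 25.0
        assert (np.diff(x) < condition.v_roll_threshold_um_s * dt).all()

    def test_subframe_dwell_yields_at_most_one_sample(self, geometry):
        tr = GroundTruthTransit(
            cell_id=0, intervals=[Interval(FREE, 1.0, 1059.0)],
            fov_intervals=[Interval(FREE, 0.01, 1059.0)],
            t_offset_s=0.0, t_elution_s=1.0, true_binding_fraction=0.0,
            v_roll_um_s=100.0,
        )
        t, x, _ = fov_positions(tr, geometry, frame_rate_hz=25.0)
        assert len(t) <= 1


class TestRenderVideo:
    def _single_cell_table(self, geometry, cfg, v_um_s=500.0, n_frames=30):
        import pandas as pd

        dt = 1.0 / cfg.frame_rate_hz
        rows = [
            (0, k, k * dt, 100.0 + v_um_s * k * dt, 200.0, FREE)
            for k in range(n_frames)
        ]
        return pd.DataFrame(
            rows, columns=["cell_id", "frame", "t_s", "x_um", "y_um", "state"]
        )

    def test_noiseless_intensity_is_conserved(self, geometry):
        cfg = RenderConfig(noise_sigma=0.0, seed=0)
        table = self._single_cell_table(geometry, cfg)
        # keep only frames where the spot sits fully inside the image
        margin = 4 * cfg.psf_sigma_px * cfg.pixel_size_um
        table = table[table["x_um"] < cfg.image_width_px * cfg.pixel_size_um - margin]
        stack = render_video(table, cfg)
        integrated = stack.astype(float).sum(axis=(1, 2)) - (
            cfg.background_level * stack.shape[1] * stack.shape[2]
        )
        assert np.ptp(integrated) / integrated.mean() < 0.01

    def test_same_seed_bit_identical(self, geometry):
        cfg = RenderConfig(seed=42)
        table = self._single_cell_table(geometry, cfg)
        a = render_video(table, cfg)
        b = render_video(table, cfg)
        assert np.array_equal(a, b)

    def test_single_cell_round_trip_speed(self, geometry, condition, tracker_cfg):
        """Track a rendered constant-velocity cell: the recovered median
        speed lands within one pixel-per-frame of the truth."""
        from adchrom import track_stack, track_summaries

        cfg = RenderConfig(seed=3)
        v_true = 500.0
        # ~65 warm-up frames before the cell enters, then a full crossing
        import pandas as pd

        dt = 1.0 / cfg.frame_rate_hz
        rows = []
        for k in range(30):
            x = 5.0 + v_true * k * dt
            if x < cfg.image_width_px * cfg.pixel_size_um - 20:
                rows.append((0, k + 65, (k + 65) * dt, x, 240.0, FREE))
        table = pd.DataFrame(
            rows, columns=["cell_id", "frame", "t_s", "x_um", "y_um", "state"]
        )
        stack = render_video(table, cfg, n_frames=int(table["frame"].max()) + 1)
        tracks = track_stack(stack, tracker_cfg)
        summaries = track_summaries(tracks, tracker_cfg)
        best = summaries.loc[summaries["n_detections"].idxmax()]
        tol = cfg.pixel_size_um * cfg.frame_rate_hz  # 1 px per frame
        assert abs(best["v_inst_median_um_s"] - v_true) < tol

    def test_rejects_bad_pixel_size(self, geometry):
        cfg = RenderConfig(seed=0)
        cfg.pixel_size_um = -1.0
        table = self._single_cell_table(geometry, RenderConfig())
        with pytest.raises(Exception, match="pixel_size"):
            render_video(table, cfg)


def test_frame_table_has_documented_schema(condition, geometry, render_cfg):
    params = SimulationParams(n_cells=5, seed=21, t_offset_mean_s=5.0)
    transits = simulate_transits(params, condition, geometry)
    table = transits_to_frame_table(transits, geometry, render_cfg)
    assert list(table.columns) == ["cell_id", "frame", "t_s", "x_um", "y_um", "state"]
    assert (table["x_um"] >= 0).all()
    assert (table["x_um"] <= geometry.fov_length_um + 1e-6).all()
    assert table["frame"].min() >= 0
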