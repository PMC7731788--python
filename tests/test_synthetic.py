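"""Generator correctness: field calibration, kinematics, determinism."""

import numpy as np
import pytest

from csfflow.errors import EmptyRegionError, InvalidSpecError
from csfflow.geometry import circle_polygon, sample_uniform
from csfflow.synthetic import (
    CompartmentSpec,
    FlowSpec,
    build_vortex_field,
    simulate_movie,
    true_median_speed,
)


def vortex_comp(target, polarity="clockwise", center=(0.0, 0.0), radius=1.0):
    return CompartmentSpec(
        label="v",
        region=circle_polygon(center, radius),
        flow_model="vortex",
        polarity=polarity,
        median_speed_target=target,
        center=center,
        radius=radius,
    )


class TestVortexField:
    def test_zero_target_gives_null_field(self):
        s = build_vortex_field(vortex_comp(0.0))
        pts = np.array([[0.3, 0.1], [-0.5, 0.2], [0.0, 0.0]])
        assert np.all(s(pts) == 0)

    def test_clockwise_points_down_right_of_center(self):
        # package convention: clockwise => negative y-component right of center
        s = build_vortex_field(vortex_comp(10.0, polarity="clockwise"))
        v = s([[0.5, 0.0]])
        assert v[0, 1] < 0 and abs(v[0, 0]) < 1e-12
        s2 = build_vortex_field(vortex_comp(10.0, polarity="counterclockwise"))
        assert s2([[0.5, 0.0]])[0, 1] > 0

    def test_median_speed_calibration_unit_disk(self):
        # Monte-Carlo oracle: median |v| over uniform samples must hit the target
        comp = vortex_comp(10.0)
        s = build_vortex_field(comp)
        rng = np.random.default_rng(42)
        pts = sample_uniform(comp.region, 100_000, rng)
        med = np.median(np.hypot(*s(pts).T))
        assert med == pytest.approx(10.0, abs=0.1)

    def test_degenerate_region_rejected(self):
        with pytest.raises(InvalidSpecError):
            CompartmentSpec(
                label="bad",
                region=[(0, 0), (1, 0), (2, 0)],  # collinear: zero area
                flow_model="vortex",
                median_speed_target=1.0,
            )


class TestSimulateMovie:
    def test_identical_seed_bit_identical(self, vortex_spec_factory):
        spec_a = vortex_spec_factory(speed=8.0, seed=5, n_frames=10)
        spec_b = vortex_spec_factory(speed=8.0, seed=5, n_frames=10)
        ma, gta = simulate_movie(spec_a)
        mb, gtb = simulate_movie(spec_b)
        assert np.array_equal(ma.data, mb.data)
        assert gta.tracks.equals(gtb.tracks)

    def test_different_seed_differs(self, vortex_spec_factory):
        ma, _ = simulate_movie(vortex_spec_factory(speed=8.0, seed=1, n_frames=4))
        mb, _ = simulate_movie(vortex_spec_factory(speed=8.0, seed=2, n_frames=4))
        assert not np.array_equal(ma.data, mb.data)

    def test_static_tracks_have_zero_displacement(self, vortex_spec_factory):
        spec = vortex_spec_factory(speed=0.0, seed=3, n_frames=12, survival_prob=1.0)
        _, gt = simulate_movie(spec)
        for _, grp in gt.tracks.groupby("track_id"):
            assert np.ptp(grp["x_um"].to_numpy()) == 0
            assert np.ptp(grp["y_um"].to_numpy()) == 0

    def test_uniform_flow_kinematics(self):
        # 5 µm/s along +x at 30 fps: consecutive truth positions differ by 5/30 µm
        comp = CompartmentSpec(
            label="u",
            region=[(0, 0), (200, 0), (200, 60), (0, 60)],
            flow_model="uniform",
            median_speed_target=5.0,
            direction=(1.0, 0.0),
        )
        spec = FlowSpec(
            compartments=[comp],
            image_shape=(32, 100),
            n_frames=6,
            survival_prob=1.0,
            seed=9,
        )
        _, gt = simulate_movie(spec)
        for _, grp in gt.tracks.groupby("track_id"):
            if len(grp) < 2:
                continue
            dx = np.diff(grp["x_um"].to_numpy())
            dy = np.diff(grp["y_um"].to_numpy())
            assert dx == pytest.approx(5.0 / 30.0, rel=1e-9)
            assert np.all(dy == 0)

    def test_pulsatile_nets_zero_over_whole_periods(self):
        # pure pulsatile motion: displacement over integer periods cancels
        comp = CompartmentSpec(
            label="p",
            region=[(0, 0), (300, 0), (300, 100), (0, 100)],
            flow_model="static",
            median_speed_target=0.0,
        )
        spec = FlowSpec(
            compartments=[comp],
            image_shape=(52, 152),
            n_frames=25,  # frames 0..24 span two 0.4 s periods at 30 fps
            survival_prob=1.0,
            pulsatile_amplitude=4.0,
            pulsatile_freq_hz=2.5,
            seed=4,
        )
        _, gt = simulate_movie(spec)
        for _, grp in gt.tracks.groupby("track_id"):
            grp = grp.sort_values("frame")
            full = grp[grp["frame"].isin([0, 24])]
            if len(full) == 2:
                net = np.diff(full[["x_um", "y_um"]].to_numpy(), axis=0)
                assert np.abs(net).max() < 1e-6

    def test_density_stationary_across_frames(self, vortex_spec_factory):
        spec = vortex_spec_factory(speed=12.0, seed=6, n_frames=30, survival_prob=0.9)
        _, gt = simulate_movie(spec)
        counts = gt.tracks.groupby("frame").size()
        assert counts.max() == counts.min()  # dead particles replaced 1:1

    def test_overlapping_compartments_rejected(self):
        a = CompartmentSpec(label="a", region=circle_polygon((50, 50), 30), flow_model="static")
        b = CompartmentSpec(label="b", region=circle_polygon((60, 50), 30), flow_model="static")
        with pytest.raises(InvalidSpecError):
            FlowSpec(compartments=[a, b], image_shape=(64, 64))

    @pytest.mark.parametrize(
        "kw",
        [
            {"survival_prob": 0.0},
            {"n_frames": 1},
            {"particle_sigma_um": 0.5},  # < pixel_size/2 at 2 µm px
            {"frame_interval_s": 0.0},
        ],
    )
    def test_invalid_spec_rejected(self, kw, vortex_spec_factory):
        with pytest.raises(InvalidSpecError):
            vortex_spec_factory(speed=5.0, **kw)

    def test_overdense_scene_warns(self):
        comp = CompartmentSpec(
            label="dense", region=circle_polygon((40, 40), 30), flow_model="static"
        )
        spec = FlowSpec(
            compartments=[comp],
            image_shape=(40, 40),
            n_frames=2,
            particle_density=400.0,
            seed=0,
        )
        with pytest.warns(UserWarning, match="ill-posed"):
            simulate_movie(spec)


class TestTrueMedianSpeed:
    def test_static_compartment_is_zero(self, vortex_spec_factory):
        _, gt = simulate_movie(vortex_spec_factory(speed=0.0, seed=1, n_frames=5))
        assert true_median_speed(gt, "IVp") == 0.0

    def test_uniform_compartment_is_exact(self):
        comp = CompartmentSpec(
            label="u",
            region=[(0, 0), (200, 0), (200, 60), (0, 60)],
            flow_model="uniform",
            median_speed_target=5.0,
        )
        spec = FlowSpec(compartments=[comp], image_shape=(32, 100), n_frames=4, seed=2)
        _, gt = simulate_movie(spec)
        assert true_median_speed(gt, "u") == pytest.approx(5.0, rel=1e-9)

    def test_empty_region_errors(self, vortex_spec_factory):
        _, gt = simulate_movie(vortex_spec_factory(speed=5.0, seed=1, n_frames=5))
        with pytest.raises(EmptyRegionError):
            true_median_speed(gt, circle_polygon((1e5, 1e5), 1.0))
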