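"""Synthetic-scene generator: occlusion geometry, clouds, paths, recordings."""

import numpy as np
import pytest

from batrack import (
    Scene,
    build_default_array,
    estimate_toads,
    generate_flight_path,
    generate_vegetation_cloud,
    synthesise_recording,
    theoretical_toads,
)
from batrack.acoustics import CallDetection, write_wav
from batrack.simulate import (
    FoliageBlob,
    Trunk,
    circling_scene,
    corridor_scene,
    occluded_channels,
    segment_hits_trunk,
)


class TestOcclusion:
    def test_blocked_straight_through(self):
        trunk = Trunk(base=(0.0, 5.0, 0.0), radius=0.5, height=10.0)
        assert segment_hits_trunk(np.array([0, 0, 3.0]), np.array([0, 10, 3.0]), trunk)

    def test_passes_beside(self):
        trunk = Trunk(base=(0.0, 5.0, 0.0), radius=0.5, height=10.0)
        assert not segment_hits_trunk(np.array([2, 0, 3.0]), np.array([2, 10, 3.0]), trunk)

    def test_passes_over_top(self):
        trunk = Trunk(base=(0.0, 5.0, 0.0), radius=0.5, height=2.0)
        assert not segment_hits_trunk(np.array([0, 0, 3.0]), np.array([0, 10, 3.0]), trunk)

    def test_agrees_with_dense_sampling(self, rng):
        """Analytic segment–cylinder test vs 1 mm stepping on random segments."""
        trunk = Trunk(base=(0.0, 0.0, 0.0), radius=0.7, height=6.0)
        for _ in range(300):
            p = rng.uniform([-5, -5, 0], [5, 5, 8])
            q = rng.uniform([-5, -5, 0], [5, 5, 8])
            n = max(2, int(np.linalg.norm(q - p) / 0.001))
            ts = np.linspace(0, 1, n)
            pts = p + ts[:, None] * (q - p)
            r_xy = np.hypot(pts[:, 0], pts[:, 1])
            dense = bool(np.any((r_xy < trunk.radius) & (pts[:, 2] > 0) & (pts[:, 2] < 6.0)))
            analytic = segment_hits_trunk(p, q, trunk)
            if dense != analytic:
                # a graze within one step of the surface is legitimately ambiguous
                assert abs(r_xy.min() - trunk.radius) < 5e-3
            else:
                assert dense == analytic


class TestVegetationCloud:
    def test_zero_density_empty(self):
        scene = Scene(trunks=[Trunk((0, 5, 0), 0.3, 8.0)])
        cloud = generate_vegetation_cloud(scene, point_density=0.0)
        assert len(cloud) == 0

    def test_trunk_surface_point_count(self):
        trunk = Trunk((0, 5, 0), 0.5, 10.0)
        scene = Scene(trunks=[trunk], seed=3)
        cloud = generate_vegetation_cloud(
            scene, point_density=2000.0, ground_density=0.0, marker_points=0
        )
        expected = 2 * np.pi * trunk.radius * trunk.height * 2000.0
        assert len(cloud) == pytest.approx(expected, rel=0.05)

    def test_high_deviation_fraction(self):
        scene = Scene(trunks=[Trunk((0, 5, 0), 0.5, 10.0)], seed=4)
        cloud = generate_vegetation_cloud(
            scene, point_density=4000.0, high_dev_fraction=0.10, ground_density=0.0, marker_points=0
        )
        assert len(cloud) > 50_000
        frac = float((cloud.deviation > 15).mean())
        assert frac == pytest.approx(0.10, abs=0.02)

    def test_reference_markers_stamped_in(self):
        scene, _ = corridor_scene(seed=1)
        cloud = generate_vegetation_cloud(scene, point_density=100.0)
        array = build_default_array()
        for rp in scene.reference_points_in_scene(array):
            near = np.linalg.norm(cloud.points - rp, axis=1) < 0.05
            assert near.sum() >= 100

    def test_seed_reproducibility(self, tmp_path):
        scene = Scene(trunks=[Trunk((0, 5, 0), 0.4, 8.0)], seed=9)
        c1 = generate_vegetation_cloud(scene, point_density=500.0)
        c2 = generate_vegetation_cloud(scene, point_density=500.0)
        np.testing.assert_array_equal(c1.points, c2.points)
        np.testing.assert_array_equal(c1.deviation, c2.deviation)


class TestFlightPaths:
    def test_circle_standoff(self):
        scene, params = circling_scene(seed=0)
        path = generate_flight_path("circle", scene, duration=5.0, call_rate=10.0, standoff=2.0)
        trunk = scene.trunks[0]
        d = np.hypot(path.positions[:, 0] - trunk.base[0], path.positions[:, 1] - trunk.base[1])
        np.testing.assert_allclose(d, trunk.radius + 2.0, atol=0.2)

    def test_call_count(self):
        scene, _ = circling_scene(seed=0)
        path = generate_flight_path("circle", scene, duration=10.0, call_rate=10.0)
        assert len(path.times) == 100

    def test_corridor_stays_inside_polygon(self):
        from shapely.geometry import Point, Polygon

        scene, params = corridor_scene(seed=0)
        path = generate_flight_path(
            "corridor",
            scene,
            duration=16.0,
            call_rate=8.0,
            corridor_start=params["corridor_start"],
            corridor_end=params["corridor_end"],
            speed=params["speed"],
            height=params["height"],
        )
        hull = Polygon([(-11.5, 2.0), (11.5, 2.0), (11.5, 7.6), (-11.5, 7.6)])
        assert all(hull.covers(Point(p[0], p[1])) for p in path.positions)

    def test_speeds_plausible(self):
        scene, _ = circling_scene(seed=0)
        for kind in ("circle", "random-walk"):
            path = generate_flight_path(kind, scene, duration=6.0, call_rate=10.0, speed=5.0)
            sp = path.speeds()
            assert np.all(sp >= 0.5) and np.all(sp <= 15.0)

    def test_unknown_kind(self):
        scene, _ = circling_scene(seed=0)
        with pytest.raises(ValueError, match="kind"):
            generate_flight_path("helix", scene, duration=1.0, call_rate=10.0)


class TestRecordingSynthesis:
    def _short_path(self, scene, n=3):
        times = np.arange(n) / 5.0
        pts = np.tile(np.array([1.0, 6.0, 4.0]), (n, 1))
        pts[:, 0] += np.arange(n) * 0.5
        from batrack.simulate import TruePath

        return TruePath(times=times, positions=pts, call_interval=0.2, path_kind="corridor")

    def test_no_trunks_all_channels_receive(self):
        scene = Scene(seed=5)
        array = build_default_array()
        rec, truth = synthesise_recording(self._short_path(scene), array, scene, snr_db=40.0)
        assert (truth["n_occluded"] == 0).all()
        # every channel carries signal well above the noise floor
        assert (np.abs(rec.samples).max(axis=1) > 5 * rec.samples.std()).all()

    def test_source_behind_trunk_fully_occluded(self):
        # a fat trunk right in front of the source blocks every microphone
        scene = Scene(trunks=[Trunk((0.0, 4.0, 0.0), 2.5, 12.0)], seed=5)
        array = build_default_array()
        from batrack.simulate import TruePath

        path = TruePath(
            times=np.array([0.0]),
            positions=np.array([[0.0, 8.0, 4.0]]),
            call_interval=0.2,
            path_kind="corridor",
        )
        rec, truth = synthesise_recording(path, array, scene, snr_db=40.0)
        assert truth["n_occluded"].iloc[0] == 8

    def test_resynthesised_delays_match_geometry(self):
        """TOADs re-estimated from a noiseless rendering match the forward model."""
        scene = Scene(seed=6)
        array = build_default_array()
        src = np.array([2.0, 7.0, 4.0])
        from batrack.simulate import TruePath

        path = TruePath(
            times=np.array([0.0]), positions=src[None, :], call_interval=0.2, path_kind="x"
        )
        rec, _ = synthesise_recording(path, array, scene, snr_db=80.0)
        arrival = np.linalg.norm(src - array.mic_positions[array.reference_index]) / 343.0
        det = CallDetection(
            window_start=arrival - 0.008, window_end=arrival + 0.017, trigger_channel=0,
            peak_amplitude=1.0,
        )
        ts = estimate_toads(rec, det, array)
        expected = theoretical_toads(src, array)
        np.testing.assert_allclose(ts.toads, expected, atol=0.2 / rec.sample_rate)

    def test_seed_reproducible_wav_bytes(self, tmp_path):
        scene = Scene(seed=11)
        array = build_default_array()
        for name in ("a", "b"):
            rec, _ = synthesise_recording(self._short_path(scene), array, scene)
            write_wav(tmp_path / f"{name}.wav", rec)
        assert (tmp_path / "a.wav").read_bytes() == (tmp_path / "b.wav").read_bytes()
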