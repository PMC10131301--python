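"""Multilateration, error assessment, filtering, tracks and bat passes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from batrack import (
    Position3D,
    ToadSet,
    assess_errors,
    build_tracks,
    count_bat_passes,
    filter_positions,
    localise,
    speed_of_sound,
    theoretical_toads,
)
from batrack.register import RigidTransform

C = 343.0


def toadset(toads, t=0.0):
    return ToadSet(toads=np.asarray(toads, float), peak_correlations=np.ones(7), detection_time=t)


def exact_toadset(xyz, array, c=C, t=0.0):
    return toadset(theoretical_toads(np.asarray(xyz, float), array, c), t)


class TestForwardModel:
    def test_equidistant_source_zero_toad(self, array):
        # (0,0,z) is equidistant from (1,0,0) and (-1,0,0): their TOAD difference is 0
        toads = theoretical_toads(np.array([0.0, 0.0, 5.0]), array)
        assert toads[0] == pytest.approx(toads[1], abs=1e-15)

    def test_closed_form_example(self, array):
        # source (0,0,11); reference (0,0,1) at distance 10; mic0 (1,0,0) at sqrt(122)
        toads = theoretical_toads(np.array([0.0, 0.0, 11.0]), array)
        assert toads[0] == pytest.approx((np.sqrt(122) - 10) / 343, rel=1e-12)

    def test_invariance_under_joint_rotation(self, array):
        src = np.array([4.0, 2.0, 7.0])
        tf = RigidTransform.from_axis_angle((0.3, 0.2, 0.9), 1.1, (3.0, -2.0, 0.5))
        from batrack import MicArray

        rotated = MicArray(
            mic_positions=tf.apply(array.mic_positions),
            reference_index=array.reference_index,
            reference_points=tf.apply(array.reference_points),
        )
        np.testing.assert_allclose(
            theoretical_toads(src, array),
            theoretical_toads(tf.apply(src), rotated),
            atol=1e-15,
        )

    def test_speed_of_sound_model(self):
        assert speed_of_sound() == 343.0
        assert speed_of_sound(20.0) == pytest.approx(343.0, abs=1.0)
        assert speed_of_sound(0.0) == pytest.approx(331.3, abs=0.01)


class TestLocalise:
    def test_noiseless_inversion(self, array):
        src = np.array([5.0, 3.0, 2.0])
        pos = localise(exact_toadset(src, array), array)
        assert np.linalg.norm(pos.xyz - src) < 1e-6
        assert pos.valid and pos.n_mics_used == 8

    def test_round_trip_random_hemisphere(self, array, rng):
        for _ in range(20):
            r = rng.uniform(2, 20)
            phi = rng.uniform(0, 2 * np.pi)
            cosθ = rng.uniform(0.05, 1.0)
            sinθ = np.sqrt(1 - cosθ**2)
            src = r * np.array([sinθ * np.cos(phi), sinθ * np.sin(phi), cosθ])
            pos = localise(exact_toadset(src, array), array)
            assert np.linalg.norm(pos.xyz - src) < 1e-2

    def test_all_zero_toads_flagged_invalid(self, array):
        # no point is equidistant from all 8 default mics: the fit cannot
        # reach a physical residual and the position is rejected
        pos = localise(toadset(np.zeros(7)), array)
        assert not pos.valid

    def test_too_few_channels_rejected(self, array):
        t = np.full(7, np.nan)
        t[0] = 1e-4
        t[1] = -1e-4
        with pytest.raises(ValueError, match="4 valid"):
            localise(toadset(t), array)

    def test_far_source_with_noise_has_large_errors(self, array, rng):
        # 100x the aperture is far beyond the 1-10x working range
        src = np.array([0.0, 140.0, 140.0])
        t = theoretical_toads(src, array) + rng.normal(0, 1.0 / 300e3, 7)
        ts = toadset(t)
        pos = localise(ts, array, max_residual_rms=np.inf)
        assess_errors(pos, ts, array)
        total = np.hypot(pos.radial_error, pos.tangential_error)
        assert not np.isfinite(total) or total > 2.0


class TestErrorAssessment:
    def test_exact_toads_zero_errors(self, array):
        src = np.array([3.0, -4.0, 6.0])
        ts = exact_toadset(src, array)
        pos = localise(ts, array)
        r, t, m = assess_errors(pos, ts, array)
        assert r == pytest.approx(0.0, abs=1e-9)
        assert t == pytest.approx(0.0, abs=1e-9)
        assert m == pytest.approx(0.0, abs=1e-7)

    def test_four_mics_unassessable(self, array):
        src = np.array([3.0, 2.0, 5.0])
        t = theoretical_toads(src, array)
        t[3:] = np.nan  # 3 toads + reference = 4 mics
        ts = toadset(t)
        pos = localise(ts, array)
        r, tg, m = assess_errors(pos, ts, array)
        assert np.isnan(r) and np.isnan(tg) and np.isnan(m)
        assert not pos.valid

    def test_errors_grow_with_range(self, array, rng):
        """Median estimated error at 20 m exceeds that at 5 m for equal noise."""
        sigma = 2e-6
        med = {}
        for rng_m in (5.0, 20.0):
            tot = []
            for _ in range(60):
                src = rng_m * np.array([0.3, 0.5, 0.81])
                src /= np.linalg.norm(src) / rng_m
                t = theoretical_toads(src, array) + rng.normal(0, sigma, 7)
                ts = toadset(t)
                pos = localise(ts, array, max_residual_rms=np.inf)
                assess_errors(pos, ts, array)
                tot.append(np.hypot(pos.radial_error, pos.tangential_error))
            med[rng_m] = np.median(tot)
        assert med[20.0] > med[5.0]


class TestFilter:
    def _mk(self, rng_m, rad, tan, t=0.0):
        d = np.array([0.0, rng_m, 0.0])
        return Position3D(xyz=d, time=t, radial_error=rad, tangential_error=tan, n_mics_used=8)

    def test_toy_fixture_three_survivors(self):
        ranges = [1, 3, 10, 25, 4]
        errs = [0.1, 0.6, 0.2, 0.3, 0.5]
        positions = [self._mk(r, e, e, t=i) for i, (r, e) in enumerate(zip(ranges, errs))]
        kept = filter_positions(positions)
        assert len(kept) == 3
        assert [p.range_from_origin for p in kept] == [10, 25, 4]

    def test_near_boundary_excluded(self):
        assert filter_positions([self._mk(1.9, 0.1, 0.1)]) == []
        assert len(filter_positions([self._mk(2.0, 0.1, 0.1)])) == 1

    def test_far_position_kept(self):
        assert len(filter_positions([self._mk(30.0, 0.1, 0.1)])) == 1

    def test_either_error_above_cap_excludes(self):
        assert filter_positions([self._mk(5, 0.6, 0.1)]) == []
        assert filter_positions([self._mk(5, 0.1, 0.6)]) == []
        assert len(filter_positions([self._mk(5, 0.5, 0.5)])) == 1

    def test_nan_errors_excluded(self):
        assert filter_positions([self._mk(5, np.nan, np.nan)]) == []

    @given(st.lists(st.tuples(st.floats(0.1, 40), st.floats(0, 1)), max_size=12))
    def test_idempotent_and_order_independent(self, items):
        positions = [self._mk(r, e, e, t=i) for i, (r, e) in enumerate(items)]
        once = filter_positions(positions)
        twice = filter_positions(once)
        assert [id(p) for p in once] == [id(p) for p in twice]
        rev = filter_positions(positions[::-1])
        assert {id(p) for p in rev} == {id(p) for p in once}


class TestTracks:
    def _line(self, n, rate=10.0, speed=5.0, t0=0.0, offset=0.0):
        return [
            Position3D(
                xyz=np.array([offset + speed * i / rate, 5.0, 3.0]),
                time=t0 + i / rate,
                radial_error=0.1,
                tangential_error=0.1,
                n_mics_used=8,
            )
            for i in range(n)
        ]

    def test_single_consistent_path_one_track(self):
        tracks = build_tracks(self._line(10))
        assert len(tracks) == 1
        assert len(tracks[0]) == 10

    def test_time_hole_splits_track(self):
        pos = self._line(5) + self._line(5, t0=0.4 + 3.0)
        tracks = build_tracks(pos, max_gap=1.0)
        assert len(tracks) == 2

    def test_two_distant_bats_not_cross_assigned(self):
        a = self._line(8)
        b = self._line(8, offset=100.0)
        tracks = build_tracks(sorted(a + b, key=lambda p: p.time), max_speed=20.0)
        assert len(tracks) == 2
        for tr in tracks:
            xs = [p.xyz[0] for p in tr.positions]
            assert (max(xs) < 50) or (min(xs) > 50)

    def test_short_tracks_discarded(self):
        assert build_tracks(self._line(2), min_positions=3) == []


class TestBatPasses:
    def _at(self, times):
        return [
            Position3D(xyz=np.array([0, 5.0, 3.0]), time=t, n_mics_used=8) for t in times
        ]

    def test_no_positions_zero(self):
        assert count_bat_passes([]) == 0

    def test_same_window_one_pass(self):
        assert count_bat_passes(self._at([1.0, 9.0])) == 1

    def test_adjacent_windows_two_passes(self):
        assert count_bat_passes(self._at([1.0, 11.0])) == 2
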