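"""Linking, MSD computation, anomalous-exponent fits, mobility classes."""

import itertools
import math

import numpy as np
import pytest

from punctakit import synth, tracking
from punctakit.core import ImageStack
from punctakit.spots import Punctum, SegmentationResult
from punctakit.tracking import (MSDFit, Trajectory, analyze_trajectories,
                                classify_alpha, compute_msd, count_immobile,
                                fit_anomalous_exponent, link_puncta,
                                match_frame_pairs, temporal_overlay)


def seg_from_positions(frames_positions, pixel_size_nm=100.0):
    """Build a SegmentationResult from {frame: [(x_nm, y_nm), ...]}."""
    puncta, pid = [], 0
    for f, plist in frames_positions.items():
        for x, y in plist:
            puncta.append(Punctum(pid, f, x, y, np.zeros((1, 2), int), 1.0, 1.0, 0.0))
            pid += 1
    n_frames = max(frames_positions) + 1
    return SegmentationResult(puncta, n_frames, pixel_size_nm)


def brute_force_matching(p1, p2, max_dist):
    """Enumerate all gated partial matchings; minimize matched-distance +
    max_dist per unmatched detection (the linker's stated objective)."""
    n1, n2 = len(p1), len(p2)
    d = np.hypot(p1[:, None, 0] - p2[None, :, 0], p1[:, None, 1] - p2[None, :, 1])
    best_cost, best = math.inf, []
    idx2 = range(n2)
    for k in range(min(n1, n2) + 1):
        for rows in itertools.combinations(range(n1), k):
            for cols in itertools.permutations(idx2, k):
                if any(d[r, c] > max_dist for r, c in zip(rows, cols)):
                    continue
                cost = sum(d[r, c] for r, c in zip(rows, cols)) \
                    + max_dist * (n1 - k + n2 - k)
                if cost < best_cost - 1e-9:
                    best_cost, best = cost, sorted(zip(rows, cols))
    return best_cost, best


class TestMatching:
    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(0, 6, 2)
            p1 = rng.uniform(0, 2000, (n1, 2))
            p2 = rng.uniform(0, 2000, (n2, 2))
            got = sorted(match_frame_pairs(p1, p2, 500.0))
            cost_oracle, _ = brute_force_matching(p1, p2, 500.0)
            d = np.hypot(p1[:, None, 0] - p2[None, :, 0],
                         p1[:, None, 1] - p2[None, :, 1]) if n1 and n2 else None
            cost_got = sum(d[r, c] for r, c in got) + 500.0 * (n1 + n2 - 2 * len(got))
            assert cost_got == pytest.approx(cost_oracle)

    def test_gate_is_hard(self, rng):
        p1 = np.array([[0.0, 0.0]])
        p2 = np.array([[600.0, 0.0]])
        assert match_frame_pairs(p1, p2, 500.0) == []


class TestLinkPuncta:
    def test_stationary_single_trajectory(self):
        seg = seg_from_positions({t: [(5000.0, 5000.0)] for t in range(30)})
        trajs = link_puncta(seg, 1.5, 2, 0.1)
        assert len(trajs) == 1
        assert trajs[0].length_frames == 30

    def test_speed_gate_never_exceeded(self, rng):
        pos = {t: [tuple(rng.uniform(0, 20000, 2)) for _ in range(8)]
               for t in range(20)}
        trajs = link_puncta(seg_from_positions(pos), 1.5, 2, 0.1)
        for tr in trajs:
            if tr.length_frames < 2:
                continue
            df = np.diff(tr.frames)
            step = np.hypot(*np.diff(tr.positions_nm, axis=0).T)
            assert np.all(step <= 1.5 * df * 0.1 * 1000 + 1e-9)

    def test_puncta_partitioned(self, rng):
        pos = {t: [tuple(rng.uniform(0, 10000, 2)) for _ in range(5)]
               for t in range(10)}
        seg = seg_from_positions(pos)
        trajs = link_puncta(seg, 1.5, 2, 0.1)
        assert sum(tr.length_frames for tr in trajs) == len(seg.puncta)

    def test_gap_closing_bridges_missed_detection(self):
        frames = {t: [(5000.0, 5000.0)] for t in range(20) if t != 10}
        trajs = link_puncta(seg_from_positions(frames), 1.5, 2, 0.1)
        assert len(trajs) == 1
        assert trajs[0].length_frames == 19
        assert 10 not in trajs[0].frames

    def test_gap_longer_than_max_not_closed(self):
        frames = {t: [(5000.0, 5000.0)] for t in range(20) if t not in (8, 9, 10)}
        trajs = link_puncta(seg_from_positions(frames), 1.5, 2, 0.1)
        assert len(trajs) == 2


class TestMSD:
    def test_stationary_zero(self):
        tr = Trajectory(0, np.arange(10), np.tile([1000.0, 2000.0], (10, 1)))
        lags, msd = compute_msd(tr, 0.1)
        assert np.all(msd == 0.0)

    def test_linear_motion_quadratic_msd(self):
        v = 0.5  # µm/s
        t = np.arange(50)
        pos = np.column_stack([v * 1000 * t * 0.1, np.zeros(50)])
        lags, msd = compute_msd(Trajectory(0, t, pos), 0.1)
        np.testing.assert_allclose(msd, (v * lags) ** 2, rtol=1e-9)

    def test_brownian_ensemble_matches_4dt(self):
        trajs = synth.make_trajectories(200, {"diffusive": 1.0}, 300, 0.1,
                                        d_um2_s=0.01, loc_noise_nm=0.0, seed=0)
        msds = []
        for tr in trajs:
            lags, msd = compute_msd(
                Trajectory(0, np.arange(300), tr.positions_nm), 0.1)
            msds.append(msd[:10])
        mean_msd = np.mean(msds, axis=0)
        np.testing.assert_allclose(mean_msd, 4 * 0.01 * lags[:10], rtol=0.10)

    def test_gap_lags_use_available_pairs(self):
        fr = np.array([0, 1, 3, 4])
        pos = np.zeros((4, 2))
        lags, msd = compute_msd(Trajectory(0, fr, pos), 0.5)
        assert 0.5 in lags  # lag 1 supported by (0,1) and (3,4)


class TestAnomalousFit:
    def test_brownian_closed_form_6_digits(self):
        lags = np.arange(1, 21) * 0.1
        d, a = fit_anomalous_exponent(lags, 4 * 0.01 * lags, 10)
        assert a == pytest.approx(1.0, abs=1e-6)
        assert d == pytest.approx(0.01, rel=1e-6)

    def test_ballistic_closed_form(self):
        lags = np.arange(1, 21) * 0.1
        d, a = fit_anomalous_exponent(lags, 4 * 0.01 * lags**2, 10)
        assert a == pytest.approx(2.0, abs=1e-6)

    def test_constant_msd_alpha_zero(self):
        lags = np.arange(1, 11) * 0.1
        _, a = fit_anomalous_exponent(lags, np.full(10, 0.0016), 10)
        assert abs(a) < 1e-9

    def test_all_zero_degenerate(self):
        lags = np.arange(1, 11) * 0.1
        assert fit_anomalous_exponent(lags, np.zeros(10), 10) == (0.0, 0.0)


class TestClassification:
    @pytest.mark.parametrize("alpha,expected", [
        (0.05, "immobile"), (0.0999, "immobile"), (0.1, "subdiffusive"),
        (0.5, "subdiffusive"), (0.9, "diffusive"), (1.19, "diffusive"),
        (1.2, "directed"), (2.0, "directed"),
    ])
    def test_alpha_bands(self, alpha, expected):
        assert classify_alpha(alpha) == expected

    def test_short_trajectories_excluded(self):
        tr = Trajectory(0, np.arange(44), np.zeros((44, 2)))
        assert analyze_trajectories([tr], 0.1) == []

    def test_immobile_particles_classified(self):
        trajs_t = synth.make_trajectories(100, {"immobile": 1.0}, 300, 0.1,
                                          loc_noise_nm=20.0, seed=1)
        trajs = [Trajectory(i, np.arange(300), t.positions_nm)
                 for i, t in enumerate(trajs_t)]
        fits = analyze_trajectories(trajs, 0.1)
        assert count_immobile(fits) >= 90

    def test_brownian_particles_classified_diffusive(self):
        trajs_t = synth.make_trajectories(100, {"diffusive": 1.0}, 300, 0.1,
                                          d_um2_s=0.01, loc_noise_nm=0.0, seed=2)
        trajs = [Trajectory(i, np.arange(300), t.positions_nm)
                 for i, t in enumerate(trajs_t)]
        fits = analyze_trajectories(trajs, 0.1)
        classes = [f.mobility_class for f in fits]
        assert classes.count("diffusive") >= 90
        assert count_immobile(fits) <= 2
        assert 0.9 <= np.mean([f.alpha for f in fits]) <= 1.1

    def test_translation_invariance(self):
        trajs_t = synth.make_trajectories(10, {"diffusive": 1.0}, 100, 0.1, seed=3)
        trajs = [Trajectory(i, np.arange(100), t.positions_nm)
                 for i, t in enumerate(trajs_t)]
        shifted = [Trajectory(t.id, t.frames, t.positions_nm + [5e4, -3e4])
                   for t in trajs]
        a1 = [f.alpha for f in analyze_trajectories(trajs, 0.1)]
        a2 = [f.alpha for f in analyze_trajectories(shifted, 0.1)]
        np.testing.assert_allclose(a1, a2, atol=1e-9)


class TestTemporalOverlay:
    def test_identical_frames_grayscale(self):
        frame = np.random.default_rng(0).uniform(0, 100, (32, 32))
        stack = ImageStack(np.stack([frame] * 4), 100.0, 10.0)
        rgb = temporal_overlay(stack, 30.0)
        np.testing.assert_array_equal(rgb[..., 0], rgb[..., 1])
        np.testing.assert_array_equal(rgb[..., 0], rgb[..., 2])

    def test_interval_exceeding_duration_rejected(self):
        stack = ImageStack(np.zeros((3, 8, 8)), 100.0, 1.0)
        with pytest.raises(ValueError):
            temporal_overlay(stack, 30.0)

    def test_immobile_white_mobile_separated(self, small_mask):
        stack, truth = synth.make_motion_movie(
            small_mask, 6, {"immobile": 0.5, "directed": 0.5},
            v_um_s=0.2, loc_noise_nm=0.0, n_frames=301, frame_interval_s=0.1,
            noise=synth.NoiseModel(poisson=False), seed=4)
        rgb = temporal_overlay(stack, 30.0)
        for tr in truth.trajectories:
            x, y = tr.positions_nm[0] / 100.0
            iy, ix = int(round(y)), int(round(x))
            g, m = rgb[iy, ix, 1], rgb[iy, ix, 0]
            if tr.mobility_class == "immobile":
                assert m == pytest.approx(g, rel=0.10)
            else:
                assert g > 5 * max(m, 1e-6)  # left its start pixel
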