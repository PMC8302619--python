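"""Nearest-neighbour colocalization, randomization nulls, Manders coefficients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from punctakit import coloc, synth
from punctakit.core import CellMask
from punctakit.spots import segment_spots


def brute_force_nn(pa, pb):
    return np.array([np.min(np.hypot(pb[:, 0] - x, pb[:, 1] - y)) for x, y in pa])


class TestNearestNeighbourDistances:
    def test_identical_sets_zero(self):
        pts = np.array([[0.0, 0.0], [500.0, 500.0]])
        res = coloc.nearest_neighbour_distances(pts, pts)
        assert np.all(res.distances_nm == 0.0)
        assert res.colocalized_fraction == 1.0

    def test_3_4_5_triangle(self):
        res = coloc.nearest_neighbour_distances(
            np.array([[0.0, 0.0]]), np.array([[300.0, 400.0], [1000.0, 0.0]]))
        assert res.distances_nm[0] == pytest.approx(500.0)

    def test_matches_brute_force_oracle(self, rng):
        pa = rng.uniform(0, 20000, (1000, 2))
        pb = rng.permutation(pa)
        res = coloc.nearest_neighbour_distances(pa, pb)
        np.testing.assert_allclose(res.distances_nm, brute_force_nn(pa, pb))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            coloc.nearest_neighbour_distances(np.zeros((0, 2)), np.ones((3, 2)))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 60), st.integers(1, 60))
    def test_brute_force_property(self, seed, na, nb):
        r = np.random.default_rng(seed)
        pa, pb = r.uniform(0, 5000, (na, 2)), r.uniform(0, 5000, (nb, 2))
        res = coloc.nearest_neighbour_distances(pa, pb)
        np.testing.assert_allclose(res.distances_nm, brute_force_nn(pa, pb))


class TestColocalizedFraction:
    def test_count_under_criterion(self):
        res = coloc.DistanceResult(np.array([500.0, 1000.0]), 160.0, 2, 2)
        assert coloc.colocalized_fraction(res, 600.0) == 0.5

    def test_strict_inequality_at_boundary(self):
        d = np.array([160.0, 159.999])
        assert coloc.colocalized_fraction(d, 160.0) == 0.5

    def test_monotone_in_criterion(self, rng):
        d = rng.uniform(0, 2000, 500)
        fr = [coloc.colocalized_fraction(d, c) for c in (50, 160, 500, 1500)]
        assert fr == sorted(fr)

    def test_rigid_motion_invariance(self, rng):
        pa = rng.uniform(0, 10000, (100, 2))
        pb = rng.uniform(0, 10000, (120, 2))
        f0 = coloc.nearest_neighbour_distances(pa, pb).colocalized_fraction
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        shift = np.array([1234.5, -987.6])
        f1 = coloc.nearest_neighbour_distances(
            pa @ rot.T + shift, pb @ rot.T + shift).colocalized_fraction
        assert f0 == pytest.approx(f1)


class TestRandomizeNull:
    def test_constructed_coloc_gives_min_p(self, square_mask_20um, rng):
        pb = rng.uniform(2000, 18000, (80, 2))
        pa = pb + rng.uniform(-50, 50, pb.shape)  # all colocalized
        null = coloc.randomize_null(pa, pb, square_mask_20um, 100, 160.0,
                                    mode="point", seed=0)
        assert null.observed_fraction == 1.0
        assert null.p_value == pytest.approx(1 / 101)

    def test_p_value_floor(self, square_mask_20um, rng):
        pa = rng.uniform(0, 20000, (50, 2))
        pb = rng.uniform(0, 20000, (50, 2))
        null = coloc.randomize_null(pa, pb, square_mask_20um, 20, 160.0,
                                    mode="point", seed=1)
        assert null.p_value >= 1 / 21

    def test_csr_analytic_value(self, square_mask_20um, rng):
        """Mean point-mode null fraction matches 1 - exp(-λπr²) within 3 SE."""
        pa = rng.uniform(200, 19800, (300, 2))
        pb = rng.uniform(0, 20000, (500, 2))
        null = coloc.randomize_null(pa, pb, square_mask_20um, 100, 160.0,
                                    mode="point", seed=2)
        expected = coloc.csr_expected_fraction(500 / 400.0, 160.0)
        se = null.fractions.std(ddof=1) / np.sqrt(null.n_iterations)
        assert abs(null.mean_fraction - expected) < 3 * se

    def test_object_mode_preserves_shapes_and_count(self, small_mask):
        sa, sb, _ = synth.make_puncta_field(small_mask, 30, 30, 0.5, seed=3)
        seg_a, seg_b = segment_spots(sa), segment_spots(sb)
        sizes = sorted(p.n_pixels for p in seg_b.puncta)
        null = coloc.randomize_null(seg_a, seg_b, small_mask, 5, 160.0,
                                    mode="object", seed=4)
        assert len(null.fractions) == 5
        # object count and pixel-set sizes are preserved by construction:
        # relocation only translates pixel sets, so sizes cannot change
        assert sorted(p.n_pixels for p in seg_b.puncta) == sizes

    def test_cumulative_band_ordering(self, square_mask_20um, rng):
        pa = rng.uniform(0, 20000, (100, 2))
        pb = rng.uniform(0, 20000, (100, 2))
        null = coloc.randomize_null(pa, pb, square_mask_20um, 50, 160.0,
                                    mode="point", seed=5)
        assert np.all(null.ci_low <= null.ci_high + 1e-12)
        assert np.all(np.diff(null.mean_cumulative) >= 0)
        assert null.mean_cumulative[0] <= 1e-12
        assert 0.0 <= null.ci_high[-1] <= 1.0


class TestManders:
    def test_reference_covers_analysis(self, rng):
        frame = rng.uniform(0, 10, (32, 32))
        ana = np.zeros((32, 32), bool)
        ana[8:24, 8:24] = True
        assert coloc.manders_split(frame, np.ones((32, 32), bool), ana).coefficient == 1.0

    def test_zero_inside_reference(self):
        frame = np.ones((16, 16))
        ref = np.zeros((16, 16), bool)
        ref[:4] = True
        frame[ref] = 0.0
        assert coloc.manders_split(frame, ref, np.ones((16, 16), bool)).coefficient == 0.0

    def test_known_intensity_split(self):
        frame = np.full((10, 10), 30.0)
        ref = np.zeros((10, 10), bool)
        ref[:, :5] = True
        frame[ref] = 10.0
        m = coloc.manders_split(frame, ref, np.ones((10, 10), bool))
        assert m.coefficient == pytest.approx(10 * 50 / (10 * 50 + 30 * 50))

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            coloc.manders_split(np.zeros((8, 8)), np.ones((8, 8), bool),
                                np.ones((8, 8), bool))


class TestFilamentMask:
    def test_all_zero_frame_empty_mask(self):
        assert not coloc.make_filament_mask(np.zeros((32, 32))).any()

    def test_jaccard_against_generator_truth(self, square_mask_20um):
        stack, truth = synth.make_filament_image(
            square_mask_20um, 8, noise=synth.NoiseModel(poisson=False), seed=6)
        fm = coloc.make_filament_mask(stack.frame(0))
        jac = (fm & truth).sum() / (fm | truth).sum()
        assert jac >= 0.8

    def test_puncta_on_filaments_manders_one(self, square_mask_20um):
        _, truth = synth.make_filament_image(square_mask_20um, 5, seed=7)
        frame = np.where(truth, 50.0, 0.0)
        m = coloc.manders_split(frame, truth, square_mask_20um)
        assert m.coefficient == 1.0

    def test_half_on_half_off_manders(self, square_mask_20um, rng):
        _, truth = synth.make_filament_image(square_mask_20um, 5, seed=8)
        on = np.argwhere(truth)
        off = np.argwhere(~truth & square_mask_20um.mask)
        frame = np.zeros(truth.shape)
        for pts in (on[rng.choice(len(on), 200, replace=False)],
                    off[rng.choice(len(off), 200, replace=False)]):
            frame[pts[:, 0], pts[:, 1]] += 10.0
        m = coloc.manders_split(frame, truth, square_mask_20um)
        assert m.coefficient == pytest.approx(0.5, abs=0.05)


class TestColocByRegion:
    def test_construction_all_on_filaments(self, square_mask_20um, rng):
        _, truth = synth.make_filament_image(square_mask_20um, 6, seed=9)
        on = np.argwhere(truth).astype(float)
        sel = on[rng.choice(len(on), 50, replace=False)]
        pts = np.column_stack([sel[:, 1], sel[:, 0]]) * 100.0  # (x, y) nm
        res = coloc.coloc_by_region(pts, pts, {"filament": truth}, 100.0)
        assert res["filament"].n_a == 50
        assert "outside" not in res or res["outside"] is None

    def test_region_partition_restricts_candidates(self, rng):
        left = np.zeros((100, 100), bool)
        left[:, :50] = True
        right = ~left
        pa = np.array([[2000.0, 5000.0]])          # x=20px -> left region
        pb_left = np.array([[3000.0, 5000.0]])     # 10 px away, same region
        pb_right = np.array([[5100.0, 5000.0]])    # nearer but other region
        res = coloc.coloc_by_region(pa, np.vstack([pb_left, pb_right]),
                                    {"left": left, "right": right}, 100.0)
        assert res["left"].distances_nm[0] == pytest.approx(1000.0)

    def test_truth_flags_recovered_per_region(self, square_mask_20um):
        _, _, truth = synth.make_puncta_field(square_mask_20um, 200, 200, 0.5,
                                              seed=10)
        half = np.zeros((200, 200), bool)
        half[:, :100] = True
        res = coloc.coloc_by_region(truth.puncta_a_nm, truth.puncta_b_nm,
                                    {"west": half, "east": ~half}, 100.0, 160.0)
        # pooled over both regions the recovered fraction must sit inside the
        # binomial 95% CI of the construction fraction
        n = sum(r.n_a for r in res.values() if r)
        k = sum(int(r.colocalized_fraction * r.n_a) for r in res.values() if r)
        ci = 1.96 * np.sqrt(0.5 * 0.5 / n)
        assert abs(k / n - 0.5) < ci + 0.05
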