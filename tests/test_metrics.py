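"""Tests for the saliency-evaluation metrics, each against an independent
oracle on small grids."""

import numpy as np
import pytest
from scipy.stats import wasserstein_distance_nd

from retina_saliency import (
    FixationSet,
    auc_borji,
    auc_judd,
    auc_shuffled,
    cc,
    emd,
    evaluate_all,
    kldiv,
    nss,
    similarity,
)
from retina_saliency.metrics import MetricReport, _block_downsample

from conftest import exhaustive_auc


def fixset(points, h, w):
    return FixationSet(np.asarray(points), h, w)


class TestCC:
    def test_self_correlation_is_one(self, dark_sample):
        assert cc(dark_sample.density, dark_sample.density) == pytest.approx(1.0)

    def test_negation_is_minus_one(self, rng):
        a = rng.random((6, 6))
        assert cc(a, a.max() - a) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        b = np.array([[1.0, 3.0], [2.0, 4.0]])
        assert cc(a, b) == pytest.approx(0.8)

    def test_constant_input_convention(self):
        assert cc(np.ones((3, 3)), np.random.default_rng(0).random((3, 3))) == 0.0


class TestSimilarity:
    def test_identical_distributions(self, dark_sample):
        assert similarity(dark_sample.density, dark_sample.density) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        a = np.array([[1.0, 0.0]])
        b = np.array([[0.0, 1.0]])
        assert similarity(a, b) == 0.0

    def test_two_bin_example(self):
        assert similarity(np.array([[0.6, 0.4]]), np.array([[0.3, 0.7]])) == pytest.approx(0.7)

    def test_symmetry(self, rng):
        a, b = rng.random((7, 7)), rng.random((7, 7))
        assert similarity(a, b) == pytest.approx(similarity(b, a))


class TestKLDiv:
    def test_identical_distributions_give_zero(self, dark_sample):
        assert kldiv(dark_sample.density, dark_sample.density) == pytest.approx(0.0, abs=1e-9)

    def test_two_bin_scalar_oracle(self):
        got = kldiv(np.array([[0.5, 0.5]]), np.array([[0.9, 0.1]]))
        want = 0.5 * np.log(0.5 / 0.9) + 0.5 * np.log(0.5 / 0.1)
        assert got == pytest.approx(want, abs=1e-9)
        assert got == pytest.approx(0.5108, abs=5e-5)

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p, q = rng.random((5, 5)), rng.random((5, 5))
            assert kldiv(p, q) >= 0.0


class TestNSS:
    def test_constant_map_is_zero(self):
        assert nss(np.ones((4, 4)), fixset([(1, 1)], 4, 4)) == 0.0

    def test_single_peak_scalar_oracle(self):
        """2×2 map (0,0,0,1), fixation at the 1 → z = 0.75/√0.1875 = √3."""
        smap = np.array([[0.0, 0.0], [0.0, 1.0]])
        got = nss(smap, fixset([(1, 1)], 2, 2))
        assert got == pytest.approx(np.sqrt(3.0), abs=1e-12)

    def test_fixations_on_minima_give_negative_score(self, rng):
        smap = rng.random((10, 10)) + 0.5
        smap[0, 0] = 0.0
        assert nss(smap, fixset([(0, 0)], 10, 10)) < 0.0

    def test_invariant_under_positive_affine_rescale(self, dark_sample, rng):
        smap = rng.random((96, 128))
        fix = dark_sample.fixations
        assert nss(smap, fix) == pytest.approx(nss(3.0 * smap + 0.2, fix))


class TestAUCJudd:
    def test_fixations_at_unique_maximum(self, rng):
        smap = rng.random((8, 8))
        peak = np.unravel_index(smap.argmax(), smap.shape)
        assert auc_judd(smap, fixset([peak], 8, 8)) == pytest.approx(1.0)

    def test_hand_enumerated_example(self):
        """2×2 map (0.1,0.4,0.2,0.8), one fixation at 0.4 → 5/6."""
        smap = np.array([[0.1, 0.4], [0.2, 0.8]])
        assert auc_judd(smap, fixset([(0, 1)], 2, 2)) == pytest.approx(5.0 / 6.0)

    def test_constant_map_is_chance(self):
        assert auc_judd(np.ones((5, 5)), fixset([(2, 2)], 5, 5)) == 0.5

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        # enough fixations that the trapezoidal ROC through the fixation
        # thresholds converges to the pairwise-comparison area
        smap = rng.random((16, 16))
        pts = [(int(r), int(c)) for r, c in rng.integers(0, 16, size=(80, 2))]
        fix = fixset(list(dict.fromkeys(pts)), 16, 16)
        mask = np.ones(smap.size, dtype=bool)
        mask[fix.flat_indices()] = False
        oracle = exhaustive_auc(fix.values_at(smap), smap.ravel()[mask])
        assert auc_judd(smap, fix) == pytest.approx(oracle, abs=0.02)

    def test_invariant_under_positive_affine_rescale(self, rng):
        smap = rng.random((12, 12))
        fix = fixset([(2, 3), (7, 8), (11, 0)], 12, 12)
        assert auc_judd(5.0 * smap + 1.0, fix) == pytest.approx(auc_judd(smap, fix))


class TestAUCBorji:
    def test_fixations_at_unique_maximum(self, rng):
        smap = rng.random((8, 8))
        peak = np.unravel_index(smap.argmax(), smap.shape)
        for seed in (0, 1, 2):
            assert auc_borji(smap, fixset([peak], 8, 8), seed=seed) == pytest.approx(1.0)

    def test_constant_map_is_chance(self):
        got = auc_borji(np.ones((6, 6)), fixset([(1, 1), (4, 4)], 6, 6), seed=0)
        assert got == pytest.approx(0.5, abs=0.02)

    def test_matches_exhaustive_negative_oracle(self, rng):
        smap = rng.random((16, 16))
        pts = [(int(r), int(c)) for r, c in rng.integers(0, 16, size=(10, 2))]
        fix = fixset(list(dict.fromkeys(pts)), 16, 16)
        mask = np.ones(smap.size, dtype=bool)
        mask[fix.flat_indices()] = False
        oracle = exhaustive_auc(fix.values_at(smap), smap.ravel()[mask])
        got = auc_borji(smap, fix, n_splits=100, n_neg=200, seed=0)
        assert got == pytest.approx(oracle, abs=0.02)

    def test_seeded_determinism(self, rng):
        smap = rng.random((10, 10))
        fix = fixset([(1, 1), (5, 7)], 10, 10)
        assert auc_borji(smap, fix, seed=9) == auc_borji(smap, fix, seed=9)


class TestAUCShuffled:
    def test_center_prior_cancellation(self):
        """A pure central-Gaussian map scored against fixations and negatives
        drawn from that same central density is at chance."""
        from retina_saliency.center_bias import build_center_bias, central_prior
        from retina_saliency.synthetic import sample_fixations

        h, w = 96, 128
        bias = build_center_bias(central_prior(h, w), h, w)
        density = bias / bias.sum()
        fix = sample_fixations(density, 1000, seed=123)
        other = [sample_fixations(density, 1000, seed=456)]
        got = auc_shuffled(bias, fix, other, seed=0)
        assert got == pytest.approx(0.5, abs=0.05)
        # the unshuffled variant is fooled by the very same map
        assert auc_borji(bias, fix, seed=0) > 0.7

    def test_fixations_at_maximum_negatives_elsewhere(self, rng):
        smap = rng.random((8, 8))
        smap[3, 3] = 2.0
        fix = fixset([(3, 3)], 8, 8)
        other = [fixset([(0, 0), (7, 7), (1, 6)], 8, 8)]
        assert auc_shuffled(smap, fix, other, seed=0) == pytest.approx(1.0)

    def test_reduces_to_borji_under_uniform_other_fixations(self, rng):
        smap = rng.random((16, 16))
        fix = fixset([(int(r), int(c)) for r, c in rng.integers(0, 16, size=(20, 2))], 16, 16)
        uniform_other = [
            fixset([(int(r), int(c)) for r, c in rng.integers(0, 16, size=(400, 2))], 16, 16)
        ]
        shuffled = auc_shuffled(smap, fix, uniform_other, n_splits=100, n_neg=100, seed=0)
        borji = auc_borji(smap, fix, n_splits=100, n_neg=100, seed=0)
        assert shuffled == pytest.approx(borji, abs=0.03)

    def test_requires_other_fixations(self, rng):
        with pytest.raises(ValueError):
            auc_shuffled(rng.random((4, 4)), fixset([(0, 0)], 4, 4), [])


class TestEMD:
    def test_identical_distributions_give_zero(self, dark_sample):
        assert emd(dark_sample.density, dark_sample.density) == 0.0

    def test_point_masses_five_cells_apart(self):
        a = np.zeros((1, 8))
        b = np.zeros((1, 8))
        a[0, 1] = 1.0
        b[0, 6] = 1.0
        assert emd(a, b) == pytest.approx(5.0, abs=1e-9)

    def test_three_bin_linear_program_oracle(self):
        """P=(1,0,0), Q=(0,0.5,0.5), unit spacing → 0.5·1 + 0.5·2 = 1.5."""
        p = np.array([[1.0, 0.0, 0.0]])
        q = np.array([[0.0, 0.5, 0.5]])
        assert emd(p, q) == pytest.approx(1.5, abs=1e-9)

    def test_symmetry(self, rng):
        a, b = rng.random((6, 6)), rng.random((6, 6))
        assert emd(a, b) == pytest.approx(emd(b, a), abs=1e-9)

    def test_one_dimensional_cdf_oracle(self, rng):
        """On a line, optimal transport has the closed form ∫|CDF_P − CDF_Q|."""
        p = rng.random((1, 20))
        q = rng.random((1, 20))
        got = emd(p, q)
        want = np.abs(np.cumsum(p / p.sum() - q / q.sum())).sum()
        assert got == pytest.approx(want, abs=1e-9)

    def test_matches_generic_transport_solver_on_8x8(self, rng):
        p = rng.random((8, 8))
        q = rng.random((8, 8))
        yy, xx = np.mgrid[0:8, 0:8]
        pts = np.c_[yy.ravel(), xx.ravel()].astype(float)
        want = wasserstein_distance_nd(pts, pts, (p / p.sum()).ravel(), (q / q.sum()).ravel())
        assert emd(p, q) == pytest.approx(want, abs=1e-6)

    def test_block_downsample_preserves_mass(self, rng):
        arr = rng.random((96, 130))
        down = _block_downsample(arr, 16)
        assert down.shape[0] <= 16 and down.shape[1] <= 16
        assert down.sum() == pytest.approx(arr.sum())


class TestEvaluateAll:
    def test_self_comparison_identities(self, dark_sample):
        """A prediction equal to the ground-truth density achieves the ideal
        distribution-metric scores."""
        report = evaluate_all(
            dark_sample.density,
            dark_sample.density,
            dark_sample.fixations,
            other_fix=[dark_sample.fixations],
            seed=0,
            emd_grid=16,
        )
        assert report.cc == pytest.approx(1.0)
        assert report.similarity == pytest.approx(1.0)
        assert report.emd == pytest.approx(0.0, abs=1e-9)
        assert report.kldiv == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_given_seed(self, dark_sample, rng):
        smap = rng.random((96, 128))
        kwargs = dict(
            density=dark_sample.density,
            fix=dark_sample.fixations,
            other_fix=[dark_sample.fixations],
            seed=5,
            emd_grid=8,
        )
        assert evaluate_all(smap, **kwargs) == evaluate_all(smap, **kwargs)

    def test_all_fields_finite_and_in_range(self, dark_sample, rng):
        smap = rng.random((96, 128))
        report = evaluate_all(
            smap,
            dark_sample.density,
            dark_sample.fixations,
            other_fix=[dark_sample.fixations],
            seed=0,
            emd_grid=8,
        )
        d = report.to_dict()
        assert all(np.isfinite(v) for v in d.values())
        for name in ("auc_borji", "auc_judd", "auc_shuffled"):
            assert 0.0 <= d[name] <= 1.0
        assert 0.0 <= d["similarity"] <= 1.0
        assert -1.0 <= d["cc"] <= 1.0
        assert d["emd"] >= 0.0 and d["kldiv"] >= 0.0

    def test_shuffled_missing_without_other_images(self, dark_sample, rng):
        report = evaluate_all(
            rng.random((96, 128)),
            dark_sample.density,
            dark_sample.fixations,
            other_fix=[],
            seed=0,
            emd_grid=8,
        )
        assert report.auc_shuffled is None


class TestFixationSet:
    def test_rejects_out_of_bounds(self):
        with pytest.raises(ValueError):
            fixset([(5, 0)], 5, 5)
        with pytest.raises(ValueError):
            fixset([(0, -1)], 5, 5)

    def test_csv_round_trip(self, tmp_path):
        fix = fixset([(0, 1), (3, 2)], 4, 4)
        path = tmp_path / "fix.csv"
        fix.to_csv(path)
        back = FixationSet.from_csv(path, 4, 4)
        assert np.array_equal(back.points, fix.points)

    def test_direction_flags(self):
        assert MetricReport.is_improvement("cc", 0.3, 0.4)
        assert not MetricReport.is_improvement("cc", 0.4, 0.4)
        assert MetricReport.is_improvement("emd", 2.0, 1.5)
        assert not MetricReport.is_improvement("kldiv", 1.0, 1.0)
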