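"""Selective sampling: Otsu split, probability field, coverage stop rule."""

import numpy as np
import pytest
from scipy import stats

from ir2.errors import (
    DegenerateInputError,
    GeometryError,
    InfeasibleWeightingError,
)
from ir2.sampling import (
    SamplingConfig,
    build_probability_field,
    compute_coverage,
    extract_training_set,
    otsu_threshold,
    patch_slices,
    sample_patch_centers,
)


def brute_force_otsu(values, bins):
    """Independent exhaustive scan over all histogram cuts.

    Returns every cut whose between-class variance ties the maximum to within
    float rounding, so near-degenerate histograms compare fairly.
    """
    hist, edges = np.histogram(values, bins=bins,
                               range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    variances = np.full(len(hist) - 1, -np.inf)
    for i in range(len(hist) - 1):
        w0, w1 = hist[:i + 1].sum(), hist[i + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:i + 1] * centers[:i + 1]).sum() / w0
        m1 = (hist[i + 1:] * centers[i + 1:]).sum() / w1
        variances[i] = w0 * w1 * (m0 - m1) ** 2
    vmax = variances.max()
    winners = np.flatnonzero(variances >= vmax * (1 - 1e-12))
    return [edges[i + 1] for i in winners]


class TestOtsu:
    def test_perfectly_bimodal(self):
        v = np.concatenate([np.zeros(500), np.full(500, 100.0)])
        t = otsu_threshold(v)
        assert 0 < t <= 100
        assert (v > t).sum() == 500

    def test_constant_volume_rejected(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(np.full((4, 4), 3.0))

    @pytest.mark.parametrize("values,bins", [
        (np.array([1., 1., 2., 8., 9., 9.]), 8),
        (np.array([1., 1., 2., 8., 9., 9.]), 16),
        (np.array([0., 5., 5., 5., 10., 10.]), 10),
    ])
    def test_matches_exhaustive_scan(self, values, bins):
        winners = brute_force_otsu(values, bins)
        # tie policy: the implementation reports the lowest tied threshold
        assert otsu_threshold(values, bins) == pytest.approx(min(winners))

    def test_random_volumes_match_oracle(self, rng):
        for _ in range(10):
            v = rng.normal(size=500) + 5 * (rng.random(500) > 0.7)
            got = otsu_threshold(v, 64)
            assert any(got == pytest.approx(w) for w in brute_force_otsu(v, 64))


class TestProbabilityField:
    def _bimodal(self, n_f=10, n_b=90):
        return np.concatenate([np.zeros(n_b), np.full(n_f, 100.0)]).reshape(10, 10)

    def test_explicit_two_class_probabilities(self):
        v = self._bimodal(10, 90)
        f = build_probability_field(v, SamplingConfig(B=0.9))
        assert f.n_f == 10 and f.n_b == 90
        np.testing.assert_allclose(f.p[v > f.threshold], 0.09)
        np.testing.assert_allclose(f.p[v <= f.threshold], 1 / 900)

    def test_homogeneous_reduction(self, small_pair):
        data = small_pair.degraded.data[::4, ::4, ::4]
        cfg = SamplingConfig()
        f0 = build_probability_field(data, cfg)
        b_hom = f0.n_f / f0.n
        f = build_probability_field(data, SamplingConfig(B=b_hom))
        # every voxel carries the same probability, equal to 1/N up to ulp
        # rounding of the float divisions
        assert np.ptp(f.p) <= 2 * np.spacing(1.0 / data.size)
        np.testing.assert_allclose(f.p, 1.0 / data.size, rtol=1e-14)

    def test_probability_conservation(self, small_pair):
        for b in (0.0, 0.3, 0.9, 1.0):
            f = build_probability_field(small_pair.degraded.data,
                                        SamplingConfig(B=b))
            assert abs(f.p.sum() - 1.0) < 1e-9

    def test_infeasible_weighting_rejected(self):
        v = np.concatenate([np.zeros(99), [100.0]]).reshape(10, 10)
        # every voxel above threshold is the single foreground one; forcing
        # background-only mass on an all-foreground field must fail
        fg_only = np.full(100, 50.0)
        fg_only[::2] = 60.0
        with pytest.raises((InfeasibleWeightingError, DegenerateInputError)):
            build_probability_field(np.full((10, 10), 5.0), SamplingConfig())
        f = build_probability_field(v, SamplingConfig(B=1.0))
        assert f.p[v > f.threshold].sum() == pytest.approx(1.0)


class TestSampleCenters:
    def test_b1_yields_only_foreground_centers(self, small_pair):
        f = build_probability_field(small_pair.degraded.data,
                                    SamplingConfig(B=1.0))
        centers = sample_patch_centers(f, 200, (16, 64, 64), seed=0)
        assert all(f.foreground[tuple(c)] for c in centers)

    def test_foreground_fraction_matches_b(self, small_pair):
        f = build_probability_field(small_pair.degraded.data,
                                    SamplingConfig(B=0.9))
        n = 10_000
        centers = sample_patch_centers(f, n, (16, 64, 64), seed=42)
        k = sum(f.foreground[tuple(c)] for c in centers)
        lo, hi = stats.binom.interval(0.99, n, 0.9)
        assert lo <= k <= hi

    def test_containment_geometry(self, standard_pair):
        f = build_probability_field(standard_pair.degraded.data,
                                    SamplingConfig())
        centers = sample_patch_centers(f, 500, (32, 128, 128), seed=1)
        z, y, x = centers.T
        assert z.min() >= 16 and z.max() < 48
        assert y.min() >= 64 and y.max() < 192
        assert x.min() >= 64 and x.max() < 192

    def test_deterministic_under_seed(self, small_pair):
        f = build_probability_field(small_pair.degraded.data, SamplingConfig())
        a = sample_patch_centers(f, 50, (16, 64, 64), seed=9)
        b = sample_patch_centers(f, 50, (16, 64, 64), seed=9)
        np.testing.assert_array_equal(a, b)

    def test_patch_larger_than_volume_rejected(self, small_pair):
        f = build_probability_field(small_pair.degraded.data, SamplingConfig())
        with pytest.raises(GeometryError):
            sample_patch_centers(f, 10, (64, 512, 512), seed=0)


class TestCoverage:
    def test_no_centers_zero_coverage(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        assert compute_coverage([], (4, 4, 4), mask) == 0.0

    def test_single_covering_patch(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[3:5, 3:5, 3:5] = True
        assert compute_coverage([(4, 4, 4)], (6, 6, 6), mask) == 1.0

    def test_overlapping_patches_match_explicit_union(self):
        mask = np.zeros((10, 12, 12), bool)
        mask[2:8, 2:10, 2:10] = True
        centers = [(5, 4, 4), (5, 6, 6)]
        shape = (4, 4, 4)
        got = compute_coverage(centers, shape, mask)
        covered = set()
        for c in centers:
            sl = patch_slices(c, shape)
            for z in range(sl[0].start, sl[0].stop):
                for y in range(sl[1].start, sl[1].stop):
                    for x in range(sl[2].start, sl[2].stop):
                        if mask[z, y, x]:
                            covered.add((z, y, x))
        assert got == pytest.approx(len(covered) / mask.sum())

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateInputError):
            compute_coverage([], (2, 2, 2), np.zeros((4, 4, 4), bool))


class TestExtractTrainingSet:
    def test_coverage_target_reached(self, small_pair):
        cfg = SamplingConfig(patch_shape=(16, 64, 64), seed=0)
        res = extract_training_set(small_pair, cfg)
        assert res.status == "converged"
        assert res.coverage >= cfg.coverage_target

    def test_trace_non_decreasing(self, small_pair):
        cfg = SamplingConfig(patch_shape=(16, 48, 48), seed=1, max_patches=400)
        res = extract_training_set(small_pair, cfg)
        trace = np.asarray(res.coverage_trace)
        assert np.all(np.diff(trace) >= 0)

    def test_deterministic_under_seed(self, small_pair):
        cfg = SamplingConfig(patch_shape=(16, 64, 64), seed=3)
        a = extract_training_set(small_pair, cfg)
        b = extract_training_set(small_pair, cfg)
        assert [p.center for p in a.pairs] == [p.center for p in b.pairs]
        np.testing.assert_array_equal(a.pairs[0].degraded_patch,
                                      b.pairs[0].degraded_patch)

    def test_background_center_fraction_near_ten_percent(self, small_pair):
        cfg = SamplingConfig(patch_shape=(16, 48, 48), seed=5,
                             coverage_target=1.0, max_patches=600)
        res = extract_training_set(small_pair, cfg)
        n = len(res.pairs)
        assert n >= 100  # enough draws for a meaningful binomial check
        k_bg = sum(not p.is_foreground_center for p in res.pairs)
        lo, hi = stats.binom.interval(0.999, n, 0.1)
        assert lo <= k_bg <= hi

    def test_unreachable_target_flags_warning_not_exception(self, small_pair):
        cfg = SamplingConfig(patch_shape=(16, 64, 64), max_patches=3,
                             coverage_target=1.0, seed=0)
        res = extract_training_set(small_pair, cfg)
        assert res.status == "max_patches"
        assert len(res.pairs) == 3
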