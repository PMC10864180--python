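"""Quality metrics: formula oracles, invariances, surface selection, reports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from _oracles import iic_cosine_sum, nrmse_direct, pearson_direct, ssim_windowed
from ir2.errors import (
    DegenerateInputError,
    DegenerateReferenceError,
    EmptySelectionError,
)
from ir2.metrics import (
    SpectralEntropyConfig,
    evaluate_patchwise,
    information_content,
    information_gain,
    nrmse,
    pearson,
    ssim,
    surface_patch_selector,
)


class TestNRMSE:
    def test_identical_images_zero(self, rng):
        a = rng.random((4, 4))
        assert nrmse(a, a) == 0.0

    @pytest.mark.parametrize("x,y,expect", [
        ([2., 2., 2., 2.], [1., 1., 1., 1.], 1.0),
        ([2., 0.], [0., 2.], 2.0),
    ])
    def test_hand_computed_values(self, x, y, expect):
        assert nrmse(np.array(x), np.array(y)) == pytest.approx(expect)

    def test_zero_mean_reference_rejected(self):
        with pytest.raises(DegenerateReferenceError):
            nrmse(np.ones(4), np.array([1.0, -1.0, 1.0, -1.0]))


class TestPearson:
    def test_perfect_and_inverted(self, rng):
        a = rng.random((3, 3, 3))
        assert pearson(a, a) == pytest.approx(1.0)
        assert pearson(a, -a) == pytest.approx(-1.0)

    def test_hand_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 5.0, 4.0])
        assert pearson(x, y) == pytest.approx(pearson_direct(x, y), abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson(np.ones(5), np.arange(5.0))


class TestSSIM:
    def test_identical_images_one(self, rng):
        a = rng.random((16, 16))
        assert ssim(a, a, data_range=1.0) == pytest.approx(1.0)

    def test_constant_pair_closed_form(self):
        a, b, dr = 3.0, 5.0, 10.0
        c1 = (0.01 * dr) ** 2
        expect = (2 * a * b + c1) / (a ** 2 + b ** 2 + c1)
        got = ssim(np.full((16, 16), a), np.full((16, 16), b), data_range=dr)
        assert got == pytest.approx(expect, rel=1e-9)

    def test_matches_windowed_oracle(self, rng):
        for _ in range(3):
            x, y = rng.random((16, 16)), rng.random((16, 16))
            assert ssim(x, y, data_range=1.0) == pytest.approx(
                ssim_windowed(x, y, data_range=1.0), abs=1e-9)


class TestInformationContent:
    def test_constant_patch_zero(self):
        assert information_content(np.full((8, 8), 42.0)) == 0.0
        assert information_content(np.zeros((4, 8, 8))) == 0.0

    def test_entropy_bounds(self, rng):
        for _ in range(10):
            p = rng.random((8, 8))
            v = information_content(p)
            assert 0.0 <= v <= np.log(p.size) + 1e-12

    def test_matches_cosine_sum_oracle(self):
        patch = np.array([
            [1.0, 3.0, 2.0, 0.0],
            [0.0, 5.0, 1.0, 2.0],
            [4.0, 1.0, 0.0, 1.0],
            [2.0, 2.0, 3.0, 0.0],
        ])
        assert information_content(patch) == pytest.approx(
            iic_cosine_sum(patch), abs=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10 ** 6), st.floats(0.1, 100.0))
    def test_scale_invariance(self, seed, alpha):
        p = np.random.default_rng(seed).random((6, 6))
        assert information_content(alpha * p) == pytest.approx(
            information_content(p), rel=1e-8)

    def test_plane_mode_averages_planes(self, rng):
        p = rng.random((3, 8, 8))
        per_plane = [information_content(p[z]) for z in range(3)]
        assert information_content(p) == pytest.approx(np.mean(per_plane))

    def test_modes_agree_on_single_plane(self, rng):
        p = rng.random((1, 8, 8))
        a = information_content(p, SpectralEntropyConfig(mode="plane"))
        b = information_content(p, SpectralEntropyConfig(mode="volume"))
        assert a == pytest.approx(b, rel=1e-10)

    def test_dc_excluded_entropy_is_shift_invariant(self, rng):
        # adding a constant touches only the DC coefficient; entropy over the
        # non-DC spectrum must be unchanged
        from scipy import fft as sp_fft

        p = rng.random((8, 8))

        def iic_no_dc(img):
            f = sp_fft.dctn(img, type=2, norm="ortho") ** 2
            f[0, 0] = 0.0
            pr = (f / f.sum()).ravel()
            pr = pr[pr > 0]
            return -(pr * np.log(pr)).sum()

        assert iic_no_dc(p + 13.0) == pytest.approx(iic_no_dc(p), rel=1e-9)


class TestInformationGain:
    def test_identity_gain_one(self, rng):
        a = rng.random((8, 8))
        assert information_gain(a, a) == pytest.approx(1.0)

    def test_reciprocal_identity(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        assert information_gain(a, b) * information_gain(b, a) == pytest.approx(1.0)

    def test_truth_beats_degraded_at_depth(self, small_pair):
        from ir2.volume import plane_detection_depth

        depth = plane_detection_depth(small_pair.mask, small_pair.spacing_um)
        deep = np.flatnonzero(depth >= 0.6 * depth.max())
        gains = []
        for z in deep[:6]:
            t = small_pair.ground_truth.data[z, 48:112, 48:112]
            d = small_pair.degraded.data[z, 48:112, 48:112]
            if t.max() <= 2 * 10.0:
                continue
            gains.append(information_gain(t, d))
        assert gains and np.mean(gains) > 1.0

    def test_zero_reference_rejected(self, rng):
        with pytest.raises(DegenerateReferenceError):
            information_gain(rng.random((4, 4)), np.zeros((4, 4)))


class TestSurfacePatchSelector:
    def test_interior_of_solid_cube_all_qualify(self):
        v = np.zeros((20, 20, 20))
        v[2:18, 2:18, 2:18] = 100.0
        centers = surface_patch_selector(v, 50.0, max_distance_um=10.0,
                                         patch_shape=(4, 4, 4), n=20, seed=0)
        assert len(centers) == 20

    def test_distance_bound_respected_against_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        v = np.zeros((16, 16, 16))
        v[3:13, 3:13, 3:13] = 100.0 + rng.random((10, 10, 10))
        spacing = (2.0, 1.0, 1.0)
        max_d = 3.0
        centers = surface_patch_selector(v, 50.0, max_d, (4, 4, 4), 50, 0,
                                         spacing)
        mask = v > 50.0
        edge = mask & ~ndimage.binary_erosion(mask)
        edge_pts = np.argwhere(edge) * np.asarray(spacing)
        for c in centers:
            p = np.asarray(c) * np.asarray(spacing)
            nearest = np.sqrt(((edge_pts - p) ** 2).sum(1)).min()
            assert nearest <= max_d + 1e-9
            assert v[tuple(c)] > 50.0

    def test_no_candidates_rejected(self):
        # the only foreground voxel sits at the corner, outside the region
        # where a (4, 4, 4) patch can be centered
        v = np.zeros((8, 8, 8))
        v[0, 0, 0] = 10.0
        with pytest.raises(EmptySelectionError):
            surface_patch_selector(v, 5.0, 100.0, (4, 4, 4), 5, 0)


class TestEvaluatePatchwise:
    def test_truth_vs_truth_is_perfect(self, small_pair):
        t = small_pair.ground_truth.data
        centers = [(24, 80, 80), (24, 64, 96)]
        records, summary = evaluate_patchwise(
            {"degraded": t, "truth": t}, centers, (16, 48, 48),
            spacing_um=small_pair.spacing_um)
        assert len(records) == 2
        assert np.allclose(records.pearson, 1.0)
        assert np.allclose(records.ssim, 1.0)
        assert np.allclose(records.nrmse, 0.0)
        assert np.allclose(records.gain, 1.0)

    def test_ssim_degrades_with_depth(self, small_pair):
        d = small_pair.degraded.data
        t = small_pair.ground_truth.data
        centers = [(z, y, 80) for z in (12, 24, 36) for y in (64, 80, 96)]
        records, summary = evaluate_patchwise(
            {"degraded": d, "truth": t}, centers, (8, 48, 48),
            spacing_um=small_pair.spacing_um, mask=small_pair.mask,
            n_depth_bins=3)
        by_depth = records.groupby("depth_bin", observed=True).ssim.mean()
        vals = by_depth.to_numpy()
        assert len(vals) >= 2
        assert vals[-1] < vals[0]

    def test_empty_centers_rejected(self, small_pair):
        with pytest.raises(EmptySelectionError):
            evaluate_patchwise(
                {"degraded": small_pair.degraded.data,
                 "truth": small_pair.ground_truth.data},
                [], (8, 32, 32))
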