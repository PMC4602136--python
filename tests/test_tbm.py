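"""Jacobian determinants, smoothing, modulation, ROI extraction and the
synthetic TBM dataset generator."""
import numpy as np
import pytest

from strokecov.ssm import residual_from_maps, ssm_decompose
from strokecov.tbm import (
    default_brain_mask,
    gaussian_smooth,
    jacobian_determinant,
    modulate,
    roi_gmv_change,
    synth_tbm_dataset,
)
from strokecov.volume import DeformationField, GeometryError, VolumeMap


def _field(shape, fn, voxel=2.0):
    """Deformation field u(x) from a function of mm coordinates."""
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    return DeformationField(fn(idx * voxel), voxel_size_mm=voxel)


class TestJacobian:
    def test_identity_mapping(self):
        f = _field((6, 6, 6), lambda x: np.zeros_like(x, dtype=float))
        det = jacobian_determinant(f)
        assert np.allclose(det.data, 1.0)

    def test_pure_translation(self):
        f = _field((6, 6, 6), lambda x: np.ones_like(x, dtype=float) * 3.7)
        assert np.allclose(jacobian_determinant(f).data, 1.0)

    def test_uniform_scaling_two_percent(self):
        f = _field((8, 8, 8), lambda x: 0.02 * x)
        det = jacobian_determinant(f)
        assert np.allclose(det.data[1:-1, 1:-1, 1:-1], 1.02**3)
        assert det.data[2, 3, 4] == pytest.approx(1.061208, abs=1e-9)

    def test_affine_matches_matrix_determinant(self, rng):
        A = 0.05 * rng.normal(size=(3, 3))
        f = _field((8, 8, 8), lambda x: x @ A.T)
        expected = np.linalg.det(np.eye(3) + A)
        det = jacobian_determinant(f)
        assert np.allclose(det.data[1:-1, 1:-1, 1:-1], expected, atol=1e-6)

    def test_degenerate_mapping_warns_not_raises(self):
        f = _field((6, 6, 6), lambda x: -1.5 * x)  # folds space
        with pytest.warns(UserWarning, match="determinant <= 0"):
            det = jacobian_determinant(f)
        assert (det.data <= 0).any()

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError):
            jacobian_determinant(DeformationField(np.zeros((1, 4, 4, 3))))


class TestModulate:
    def test_ones_identity_zeros_annihilate(self):
        jac = VolumeMap(np.full((4, 4, 4), 1.05))
        assert np.allclose(modulate(jac, jac.with_data(np.ones((4, 4, 4)))).data, 1.05)
        assert np.allclose(modulate(jac, jac.with_data(np.zeros((4, 4, 4)))).data, 0.0)

    def test_voxelwise_product(self):
        jac = VolumeMap(np.full((4, 4, 4), 1.05))
        seg = jac.with_data(np.full((4, 4, 4), 0.5))
        assert modulate(jac, seg).data[0, 0, 0] == pytest.approx(0.525)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(GeometryError):
            modulate(VolumeMap(np.ones((4, 4, 4))), VolumeMap(np.ones((5, 5, 5))))


class TestSmoothing:
    def test_fwhm_zero_is_identity(self, rng):
        m = VolumeMap(rng.normal(size=(8, 8, 8)))
        out = gaussian_smooth(m, 0.0)
        assert np.array_equal(out.data, m.data)
        assert out.data is not m.data

    def test_constant_map_unchanged(self):
        m = VolumeMap(np.full((9, 9, 9), 3.3))
        assert np.allclose(gaussian_smooth(m, 12.0).data, 3.3, atol=1e-12)

    def test_sum_preserved(self, rng):
        m = VolumeMap(rng.normal(size=(11, 11, 11)), 2.0)
        out = gaussian_smooth(m, 12.0)
        assert abs(out.data.sum() - m.data.sum()) <= 1e-6 * abs(m.data.sum())

    def test_impulse_matches_dense_convolution_oracle(self):
        # brute-force dense 3-D convolution on an 11^3 grid as oracle:
        # discrete Gaussian kernel truncated at 4 sigma, symmetric padding
        voxel, fwhm = 2.0, 12.0
        sigma = fwhm / np.sqrt(8 * np.log(2)) / voxel
        m = np.zeros((11, 11, 11))
        m[5, 5, 5] = 1.0
        r = int(4.0 * sigma + 0.5)
        x = np.arange(-r, r + 1)
        k1 = np.exp(-(x**2) / (2 * sigma**2))
        k1 /= k1.sum()
        k3 = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        padded = np.pad(m, r, mode="symmetric")
        oracle = np.zeros_like(m)
        for i in range(11):
            for j in range(11):
                for l in range(11):
                    oracle[i, j, l] = np.sum(
                        padded[i : i + 2 * r + 1, j : j + 2 * r + 1, l : l + 2 * r + 1] * k3
                    )
        out = gaussian_smooth(VolumeMap(m, voxel), fwhm)
        assert np.allclose(out.data, oracle, atol=1e-8)

    def test_linearity(self, rng):
        x = VolumeMap(rng.normal(size=(8, 8, 8)))
        y = x.with_data(rng.normal(size=(8, 8, 8)))
        lhs = gaussian_smooth(x.with_data(2.0 * x.data + 3.0 * y.data), 8.0).data
        rhs = 2.0 * gaussian_smooth(x, 8.0).data + 3.0 * gaussian_smooth(y, 8.0).data
        assert np.allclose(lhs, rhs, atol=1e-8)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(VolumeMap(np.ones((4, 4, 4))), -1.0)


class TestRoiChange:
    def test_jacobian_mode_subtracts_one(self):
        m = VolumeMap(np.full((4, 4, 4), 1.01))
        roi = m.with_data(np.ones((4, 4, 4)))
        assert roi_gmv_change(m, roi, mode="jacobian") == pytest.approx(0.01)

    def test_change_mode_mean(self):
        arr = np.zeros((4, 4, 4))
        roi = np.zeros((4, 4, 4))
        arr[0, 0, 0], arr[1, 0, 0] = 0.02, 0.04
        roi[0, 0, 0] = roi[1, 0, 0] = 1
        m = VolumeMap(arr)
        assert roi_gmv_change(m, m.with_data(roi), mode="change") == pytest.approx(0.03)

    def test_empty_roi_rejected(self):
        m = VolumeMap(np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            roi_gmv_change(m, m.with_data(np.zeros((4, 4, 4))))


class TestSynthDataset:
    def test_determinism(self, small_mask):
        a, _ = synth_tbm_dataset(4, n_patterns=2, seed=9, mask=small_mask)
        b, _ = synth_tbm_dataset(4, n_patterns=2, seed=9, mask=small_mask)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.data, mb.data)

    def test_opposite_loadings_give_opposite_maps(self, small_mask):
        maps, truth = synth_tbm_dataset(2, n_patterns=1, seed=0, mask=small_mask, noise_sd=0.0)
        sel = small_mask.data > 0
        d0 = maps[0].data[sel] - 1.0
        d1 = maps[1].data[sel] - 1.0
        # both maps are multiples of the single shared pattern
        r = np.corrcoef(d0, d1)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-10

    def test_patterns_orthonormal_over_mask(self, small_mask):
        _, truth = synth_tbm_dataset(5, n_patterns=3, seed=1, mask=small_mask)
        sel = small_mask.data > 0
        P = np.stack([p.data[sel] for p in truth.patterns], axis=1)
        G = P.T @ P / sel.sum()  # unit-RMS columns -> identity Gram matrix
        assert np.allclose(G, np.eye(3), atol=1e-10)

    def test_loading_behavior_correlation(self, small_mask, rng):
        behavior = rng.normal(size=200)
        _, truth = synth_tbm_dataset(
            200, n_patterns=1, seed=5, mask=small_mask,
            behavior=behavior, behavior_corr=0.8, behavior_pattern=0,
        )
        r = np.corrcoef(truth.loadings[:, 0], behavior)[0, 1]
        assert r == pytest.approx(0.8, abs=0.1)

    def test_invalid_correlation_rejected(self, small_mask, rng):
        with pytest.raises(ValueError):
            synth_tbm_dataset(
                10, n_patterns=1, seed=0, mask=small_mask,
                behavior=rng.normal(size=10), behavior_corr=1.5, behavior_pattern=0,
            )

    def test_embedded_pattern_recovered_by_leading_eigenimage(self, rng):
        # noise at 25% of pattern amplitude, n >= 20 subjects
        mask = default_brain_mask((24, 24, 24), 2.0)
        maps, truth = synth_tbm_dataset(24, n_patterns=1, seed=11, mask=mask, noise_sd=0.25)
        decomp = ssm_decompose(residual_from_maps(maps, mask))
        sel = mask.data > 0
        r = np.corrcoef(decomp.eigenimages[0], truth.patterns[0].data[sel])[0, 1]
        assert abs(r) >= 0.9
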