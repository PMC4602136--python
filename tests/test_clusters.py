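"""Percentile thresholding, connected components, lesion density and
overlap volumetrics, with brute-force oracles on toy grids."""
import numpy as np
import pytest

from strokecov.clusters import (
    connected_clusters,
    lesion_density,
    lesion_volume,
    overlap_percentages,
    overlap_volumetrics,
    threshold_eigenimage,
)
from strokecov.volume import GeometryError, VolumeMap


def _vol(arr, voxel=2.0):
    return VolumeMap(np.asarray(arr, dtype=float), voxel)


def brute_force_flood_fill(binary, connectivity):
    """Oracle labeling by explicit flood fill."""
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                order = abs(dx) + abs(dy) + abs(dz)
                if order == 0:
                    continue
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    labels = np.zeros_like(binary, dtype=int)
    nxt = 0
    for seed in zip(*np.where(binary)):
        if labels[seed]:
            continue
        nxt += 1
        stack = [seed]
        labels[seed] = nxt
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in offs:
                p = (x + dx, y + dy, z + dz)
                if all(0 <= c < s for c, s in zip(p, binary.shape)):
                    if binary[p] and not labels[p]:
                        labels[p] = nxt
                        stack.append(p)
    return labels


class TestThreshold:
    def test_uniform_values_one_voxel_per_tail(self):
        # values 1..100 laid out on a grid: P1/P99 leave exactly one voxel each
        arr = np.arange(1.0, 101.0).reshape(4, 5, 5)
        vol = _vol(arr)
        mask = vol.with_data(np.ones_like(arr))
        low, high = threshold_eigenimage(vol, mask, 1, 99)
        assert low.data.sum() == 1
        assert high.data.sum() == 1
        assert arr[low.data > 0][0] == 1.0
        assert arr[high.data > 0][0] == 100.0

    def test_symmetric_values_equal_tails(self, rng):
        vals = rng.normal(size=500)
        arr = np.concatenate([vals, -vals]).reshape(10, 10, 10)
        vol = _vol(arr)
        mask = vol.with_data(np.ones_like(arr))
        low, high = threshold_eigenimage(vol, mask, 2, 98)
        assert low.data.sum() == high.data.sum()

    def test_percentiles_computed_in_mask_only(self):
        arr = np.zeros((4, 5, 5))
        arr.reshape(-1)[:100] = np.arange(1.0, 101.0)
        mask = np.zeros_like(arr)
        mask.reshape(-1)[:100] = 1
        arr.reshape(-1)[100:] = 1e6  # extreme values outside the mask
        low, high = threshold_eigenimage(_vol(arr), _vol(mask), 1, 99)
        assert low.data.sum() == 1 and high.data.sum() == 1

    def test_constant_image_empty_tails_with_warning(self):
        vol = _vol(np.ones((4, 4, 4)))
        mask = vol.with_data(np.ones((4, 4, 4)))
        with pytest.warns(UserWarning, match="degenerate"):
            low, high = threshold_eigenimage(vol, mask, 1, 99)
        assert low.data.sum() == 0 and high.data.sum() == 0

    def test_invalid_percentiles_rejected(self):
        vol = _vol(np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            threshold_eigenimage(vol, vol, 99, 1)


class TestConnectedClusters:
    def test_extent_threshold_discards_small_blob(self):
        arr = np.zeros((8, 8, 8))
        arr[:31].reshape(-1)[:31] = 0  # build a 31-voxel line blob
        arr[0, 0, :8] = 1
        arr[0, 1, :8] = 1
        arr[0, 2, :8] = 1
        arr[0, 3, :7] = 1  # 31 voxels
        ct = connected_clusters(_vol(arr), connectivity=6, k_min=32)
        assert len(ct) == 0

    def test_exact_extent_threshold_and_volume(self):
        arr = np.zeros((8, 8, 8))
        arr[0:2, 0:4, 0:4] = 1  # 32-voxel blob
        ct = connected_clusters(_vol(arr, voxel=2.0), connectivity=6, k_min=32)
        assert len(ct) == 1
        assert ct.table.loc[0, "size_vox"] == 32
        assert ct.table.loc[0, "volume_cc"] == pytest.approx(0.256)

    def test_corner_touching_blobs_by_connectivity(self):
        arr = np.zeros((5, 5, 5))
        arr[0, 0, 0] = 1
        arr[1, 1, 1] = 1  # touch only at a corner
        six = connected_clusters(_vol(arr), connectivity=6, k_min=1)
        twentysix = connected_clusters(_vol(arr), connectivity=26, k_min=1)
        assert len(six) == 2
        assert len(twentysix) == 1

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_labeling_matches_brute_force_flood_fill(self, connectivity, rng):
        for _ in range(100):
            binary = rng.random((8, 8, 8)) < 0.25
            ct = connected_clusters(_vol(binary.astype(float)), connectivity, k_min=1)
            oracle = brute_force_flood_fill(binary, connectivity)
            n_oracle = oracle.max()
            assert len(ct) == n_oracle
            # same partition: label maps agree up to renaming
            lab = np.asarray(ct.label_map.data)
            for k in range(1, n_oracle + 1):
                sel = oracle == k
                assert np.unique(lab[sel]).size == 1

    def test_sorted_by_size_and_peak_reported(self, rng):
        arr = np.zeros((10, 10, 10))
        arr[0:2, 0:2, 0:2] = 1  # 8 voxels
        arr[5:9, 5:9, 5:9] = 1  # 64 voxels
        vals = _vol(rng.normal(size=(10, 10, 10)))
        ct = connected_clusters(_vol(arr), connectivity=6, k_min=1, values=vals)
        assert list(ct.table["size_vox"]) == [64, 8]
        assert {"peak_x_mm", "peak_value"} <= set(ct.table.columns)


class TestLesionMaps:
    def test_density_fraction_and_threshold(self):
        base = np.zeros((4, 4, 4))
        lesions = []
        for i in range(8):
            arr = base.copy()
            if i < 2:
                arr[0, 0, 0] = 1  # 2/8 = 0.25 > 0.20
            if i < 1:
                arr[1, 1, 1] = 1  # 1/8 = 0.125 <= 0.20
            lesions.append(_vol(arr))
        dmap = lesion_density(lesions, threshold=0.20)
        assert dmap.density.data[0, 0, 0] == pytest.approx(0.25)
        assert dmap.thresholded.data[0, 0, 0] == 1
        assert dmap.thresholded.data[1, 1, 1] == 0

    def test_zero_threshold_gives_union(self):
        a = np.zeros((3, 3, 3)); a[0, 0, 0] = 1
        b = np.zeros((3, 3, 3)); b[2, 2, 2] = 1
        dmap = lesion_density([_vol(a), _vol(b)], threshold=0.0)
        assert dmap.thresholded.data.sum() == 2

    def test_lesion_volume(self):
        arr = np.zeros((10, 10, 10))
        arr.reshape(-1)[:125] = 1
        assert lesion_volume(_vol(arr, voxel=2.0)) == pytest.approx(1.0)
        assert lesion_volume(_vol(np.zeros((4, 4, 4)))) == 0.0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            lesion_volume(_vol(np.full((3, 3, 3), 0.5)))

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(GeometryError):
            lesion_density([_vol(np.ones((3, 3, 3))), _vol(np.ones((4, 4, 4)))])


class TestOverlap:
    def test_printed_percentage_arithmetic(self):
        # a 7.10 cc overlap on a 105.7 cc lesion map covers 6.7% of it
        pol, _ = overlap_percentages(7.10, 105.7, 10.9)
        assert round(pol, 1) == 6.7

    def _cluster_table(self, label_arr, voxel=2.0):
        from strokecov.clusters import connected_clusters

        return connected_clusters(_vol(label_arr, voxel), connectivity=6, k_min=1)

    def test_disjoint_and_contained(self):
        clus = np.zeros((6, 6, 6)); clus[0:2, 0:2, 0:2] = 1
        ct = self._cluster_table(clus)
        far = np.zeros((6, 6, 6)); far[4:6, 4:6, 4:6] = 1
        cover = np.zeros((6, 6, 6)); cover[0:3, 0:3, 0:3] = 1
        d_far = lesion_density([_vol(far)], 0.1, subgroup="far")
        d_cover = lesion_density([_vol(cover)], 0.1, subgroup="cover")
        rep = overlap_volumetrics(ct, [d_far, d_cover])
        far_row = rep[rep.subgroup == "far"].iloc[0]
        cover_row = rep[rep.subgroup == "cover"].iloc[0]
        assert far_row.overlap_cc == 0.0
        assert far_row.pct_of_cluster == 0.0
        assert cover_row.pct_of_cluster == 100.0

    def test_overlap_symmetry_in_cc(self):
        a = np.zeros((6, 6, 6)); a[0:3, 0:3, 0:3] = 1
        b = np.zeros((6, 6, 6)); b[1:4, 1:4, 1:4] = 1
        ct_a = self._cluster_table(a)
        ct_b = self._cluster_table(b)
        d_a = lesion_density([_vol(a)], 0.1, subgroup="a")
        d_b = lesion_density([_vol(b)], 0.1, subgroup="b")
        ov_ab = overlap_volumetrics(ct_a, [d_b]).iloc[0].overlap_cc
        ov_ba = overlap_volumetrics(ct_b, [d_a]).iloc[0].overlap_cc
        assert ov_ab == pytest.approx(ov_ba)

    def test_overlap_bounded_by_both_volumes(self, rng):
        arr = (rng.random((8, 8, 8)) < 0.4).astype(float)
        les = (rng.random((8, 8, 8)) < 0.3).astype(float)
        ct = self._cluster_table(arr)
        dm = lesion_density([_vol(les)], 0.1, subgroup="x")
        rep = overlap_volumetrics(ct, [dm])
        assert (rep.overlap_cc <= np.minimum(rep.cluster_cc, rep.lesion_map_cc) + 1e-12).all()
        assert rep.pct_of_cluster.between(0, 100).all()
        assert rep.pct_of_lesion.between(0, 100).all()

    def test_low_tail_size_bounded_by_percentile(self, rng):
        arr = rng.normal(size=(12, 12, 12))
        vol = _vol(arr)
        mask = vol.with_data(np.ones_like(arr))
        low, _ = threshold_eigenimage(vol, mask, 1, 99)
        n_mask = int(mask.data.sum())
        assert low.data.sum() <= n_mask * 0.01 + 1
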