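import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import parenchymaseg as ps
from parenchymaseg.errors import BalanceError, DegenerateInputError, GridError
from parenchymaseg.labelgen import (
    balance_addresses,
    build_labeled_dataset,
    cross_shaped_verify,
    expand_patch,
    extract_lung_components,
    intersect_volumes,
    kmeans_two_class,
    run_single_clustering,
    split_into_patches,
)


def optimal_two_partition(values):
    """Oracle: exhaustive threshold sweep minimizing within-cluster SSE.

    For 1-D data the optimal 2-means partition is a threshold partition of
    the sorted values, so trying every split point is exact.
    """
    v = np.sort(np.asarray(values, dtype=float))
    best, best_cost = None, np.inf
    for cut in range(1, len(v)):
        lo, hi = v[:cut], v[cut:]
        cost = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if cost < best_cost:
            best_cost, best = cost, v[cut - 1]
    return best  # threshold: values <= best are "low"


class TestSplitIntoPatches:
    def test_one_slice_gives_4096_records(self):
        grid, rec = split_into_patches(np.zeros((1, 512, 512)), 8)
        assert grid.n_patches == 4096 == len(rec)

    def test_gridding_is_a_partition(self):
        rng = np.random.default_rng(0)
        vox = rng.normal(size=(2, 64, 64))
        grid, rec = split_into_patches(vox, 8)
        # sum of per-patch means * patch area == total sum (every pixel once)
        assert np.isclose(rec.mean.sum() * 64, vox.sum(), rtol=1e-6)
        assert rec.min.min() == pytest.approx(vox.min(), rel=1e-6)

    def test_constant_slice_records(self):
        _, rec = split_into_patches(np.full((1, 16, 16), -1000.0), 8)
        assert np.all(rec.mean == -1000) and np.all(rec.min == -1000)

    def test_mean_and_min_per_block(self):
        vox = np.zeros((1, 16, 16))
        vox[0, :8, :8] = [[i * 8 + j for j in range(8)] for i in range(8)]
        _, rec = split_into_patches(vox, 8)
        assert rec.mean[0, 0, 0] == pytest.approx(31.5)
        assert rec.min[0, 0, 0] == 0

    @pytest.mark.parametrize("shape", [(1, 100, 512), (1, 512, 100)])
    def test_non_divisible_dims_raise(self, shape):
        with pytest.raises(GridError):
            split_into_patches(np.zeros(shape), 8)


class TestKMeansTwoClass:
    def test_known_partition(self):
        high = kmeans_two_class([0, 1, 10, 11])
        np.testing.assert_array_equal(high, [False, False, True, True])

    def test_two_points(self):
        high = kmeans_two_class([-1000, 40])
        np.testing.assert_array_equal(high, [False, True])

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateInputError):
            kmeans_two_class([5, 5, 5])

    def test_agrees_with_exhaustive_partition_search(self):
        """Lloyd's algorithm with min/max init matches the exact optimal
        1-D two-cluster partition on 1000 random small inputs."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(2, 13)
            v = np.round(rng.normal(0, 100, n), 1)
            if np.all(v == v[0]):
                continue
            high = kmeans_two_class(v)
            thr = optimal_two_partition(v)
            np.testing.assert_array_equal(high, v > thr)

    def test_matches_sklearn_kmeans_centroids(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(7)
        v = np.concatenate([rng.normal(-900, 30, 50), rng.normal(50, 30, 50)])
        high = kmeans_two_class(v)
        sk = KMeans(n_clusters=2, n_init=10, random_state=0).fit(v.reshape(-1, 1))
        sk_high = sk.labels_ == np.argmax(sk.cluster_centers_.ravel())
        np.testing.assert_array_equal(high, sk_high)


class TestCrossShapedVerify:
    def test_center_of_ring_kept(self):
        low = np.zeros((3, 3), dtype=bool)
        low[1, 1] = True
        assert cross_shaped_verify(low)[1, 1]

    def test_border_low_patch_always_discarded(self):
        low = np.ones((4, 4), dtype=bool)
        low[1:3, 1:3] = False
        kept = cross_shaped_verify(low)
        assert not kept.any()  # all low patches are on the border

    def test_all_low_column_below_discards(self):
        # low patch with highs left/right/up but nothing high below
        low = np.zeros((4, 3), dtype=bool)
        low[1, 1] = True
        low[2, 1] = True
        low[3, 1] = True
        kept = cross_shaped_verify(low)
        assert not kept[1, 1]

    @given(st.integers(0, 2**16 - 1))
    @settings(max_examples=50, deadline=None)
    def test_never_keeps_border_patches(self, bits):
        low = np.array([(bits >> i) & 1 for i in range(16)], dtype=bool).reshape(4, 4)
        kept = cross_shaped_verify(low)
        assert not kept[0].any() and not kept[-1].any()
        assert not kept[:, 0].any() and not kept[:, -1].any()
        # brute-force cross check on every interior cell
        for i in range(1, 3):
            for j in range(1, 3):
                expect = (low[i, j] and (~low[i, :j]).any() and (~low[i, j + 1:]).any()
                          and (~low[:i, j]).any() and (~low[i + 1:, j]).any())
                assert kept[i, j] == expect


class TestClusteringPipeline:
    def test_single_clustering_covers_parenchyma(self, clean_phantom):
        _, rec = split_into_patches(clean_phantom.volume, 8)
        gt_cells = ps.sweeps.patch_grid_ground_truth(clean_phantom.gt_parenchyma, 8)
        interior = gt_cells.copy()
        for stat in ("mean", "min"):
            kept = run_single_clustering(rec, stat)
            # every fully-parenchyma cell must survive clustering+verification
            frac = kept[gt_cells].mean()
            assert frac > 0.9, (stat, frac)

    def test_pure_air_volume_degenerate(self):
        _, rec = split_into_patches(np.full((1, 64, 64), -1000.0), 8)
        with pytest.raises(DegenerateInputError):
            run_single_clustering(rec, "mean")

    def test_intersection_idempotent_and_disjoint(self):
        rng = np.random.default_rng(0)
        a = rng.random((2, 4, 4)) > 0.5
        np.testing.assert_array_equal(intersect_volumes(a, a), a)
        assert not intersect_volumes(a, ~a).any()

    def test_intersection_beats_either_branch_on_phantom(self, clean_phantom):
        _, rec = split_into_patches(clean_phantom.volume, 8)
        gt_cells = ps.sweeps.patch_grid_ground_truth(clean_phantom.gt_parenchyma, 8)
        km = run_single_clustering(rec, "mean")
        kn = run_single_clustering(rec, "min")
        inter = intersect_volumes(km, kn)
        acc = lambda m: (m == gt_cells).mean()
        assert acc(inter) >= max(acc(km), acc(kn))


class TestExtractLungComponents:
    def test_size_filter_keeps_large_blob_only(self):
        mask = np.zeros((1, 20, 20), dtype=bool)
        mask[0, 2:12, 2:12] = True      # 100 cells
        mask[0, 15:16, 15:18] = True    # 3 cells
        out = extract_lung_components(mask, min_size_frac=10 / 400, max_components=2)
        assert out.sum() == 100

    def test_two_equal_lungs_both_retained(self):
        mask = np.zeros((1, 10, 20), dtype=bool)
        mask[0, 2:8, 2:8] = True
        mask[0, 2:8, 12:18] = True
        out = extract_lung_components(mask, min_size_frac=0.01)
        assert out.sum() == 72

    def test_speckle_field_removed(self):
        mask = np.zeros((1, 16, 16), dtype=bool)
        mask[0, ::4, ::4] = True
        out = extract_lung_components(mask, min_size_frac=0.01)
        assert not out.any()

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            out = extract_lung_components(np.zeros((1, 4, 4), dtype=bool))
        assert not out.any()


class TestExpandPatch:
    def test_interior_center_block_preserved(self):
        rng = np.random.default_rng(0)
        vox = rng.normal(size=(1, 64, 64))
        win = expand_patch(vox, (0, 4, 4))
        np.testing.assert_allclose(win[12:20, 12:20], vox[0, 32:40, 32:40], rtol=1e-6)

    def test_corner_address_padded_with_air(self):
        vox = np.zeros((1, 64, 64))
        win = expand_patch(vox, (0, 0, 0))
        assert np.all(win[:12, :] == -1024)
        assert np.all(win[:, :12] == -1024)
        assert np.all(win[12:, 12:] == 0)

    def test_adjacent_windows_overlap_24_columns(self):
        vox = np.arange(64 * 64, dtype=float).reshape(1, 64, 64)
        a = expand_patch(vox, (0, 3, 3))
        b = expand_patch(vox, (0, 3, 4))
        np.testing.assert_array_equal(a[:, 8:], b[:, :24])


class TestBuildLabeledDataset:
    def test_balance_is_exact_and_deterministic(self, clean_phantom):
        labeler = ps.WeakPatchLabeler(random_state=0).fit(clean_phantom.volume)
        ds1 = labeler.transform(clean_phantom.volume)
        ds2 = labeler.transform(clean_phantom.volume)
        n_lp, n_nlp = ds1.counts
        assert n_lp == n_nlp > 0
        np.testing.assert_array_equal(ds1.addresses, ds2.addresses)

    def test_lp_patches_center_on_parenchyma(self, clean_phantom):
        """Every LP patch's central 8x8 block is parenchyma-majority."""
        ds = ps.WeakPatchLabeler(random_state=0).fit_transform(clean_phantom.volume)
        lp = ds.patches[ds.labels == 1]
        centers = lp[:, 12:20, 12:20]
        frac_parenchyma = (np.abs(centers - (-850.0)) < 1.0).mean(axis=(1, 2))
        assert np.all(frac_parenchyma > 0.5)
        assert frac_parenchyma.mean() > 0.9

    def test_empty_lp_mask_warns_and_returns_empty(self):
        vox = np.zeros((1, 32, 32))
        with pytest.warns(UserWarning, match="no LP"):
            ds = build_labeled_dataset(vox, np.zeros((1, 4, 4), dtype=bool))
        assert len(ds) == 0

    def test_balance_error_when_too_few_negatives(self):
        lp = np.argwhere(np.ones((1, 4, 4), dtype=bool))
        nlp = lp[:3]
        with pytest.raises(BalanceError):
            balance_addresses(lp, nlp, seed=0)

    def test_end_to_end_patch_labels_match_phantom_gt(self, clean_phantom):
        """On a noise-free phantom the weak labels agree with the
        patch-majority ground truth at over 99%."""
        labeler = ps.WeakPatchLabeler(random_state=0).fit(clean_phantom.volume)
        gt_cells = ps.sweeps.patch_grid_ground_truth(clean_phantom.gt_parenchyma, 8)
        agreement = (labeler.lp_mask_ == gt_cells).mean()
        assert agreement >= 0.99

    def test_high_intensity_lesion_cells_excluded_from_lp(self, lesion_phantom):
        labeler = ps.WeakPatchLabeler(random_state=0).fit(lesion_phantom.volume)
        lesion_cells = ps.sweeps.patch_grid_ground_truth(lesion_phantom.gt_lesions, 8)
        assert not (labeler.lp_mask_ & lesion_cells).any()
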