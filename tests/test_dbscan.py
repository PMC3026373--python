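import numpy as np
import pytest
from scipy import ndimage

from dermseg import (
    BinaryMask,
    DbscanParams,
    dbscan,
    eps_neighborhood,
    expand_cluster,
    generate_binary_blobs,
    random_mask,
    select_lesion_mask,
)
from dermseg.dbscan_seg import BACKGROUND, NOISE, UNCLASSIFIED, disc_offsets, _neighbor_counts

from oracles import assert_dbscan_matches_closure, disc_lattice_count


def full_mask(h, w):
    return BinaryMask(np.ones((h, w), dtype=bool))


class TestEpsNeighborhood:
    def test_zero_radius_returns_singleton(self):
        assert eps_neighborhood(full_mask(5, 5), (2, 3), 0) == {(2, 3)}

    @pytest.mark.parametrize("eps", [1.0, 1.5, 2.5, 5.0])
    def test_interior_disc_count_matches_lattice_enumeration(self, eps):
        mask = full_mask(25, 25)
        assert len(eps_neighborhood(mask, (12, 12), eps)) == disc_lattice_count(eps)

    def test_all_negative_mask_gives_empty_set(self):
        mask = BinaryMask(np.zeros((8, 8), dtype=bool))
        assert eps_neighborhood(mask, (4, 4), 3.0) == set()

    def test_border_truncates_disc(self):
        mask = full_mask(10, 10)
        corner = eps_neighborhood(mask, (0, 0), 2.0)
        interior = eps_neighborhood(mask, (5, 5), 2.0)
        assert len(corner) < len(interior)
        assert all(0 <= r < 10 and 0 <= c < 10 for r, c in corner)

    def test_out_of_bounds_pixel_rejected(self):
        with pytest.raises(ValueError):
            eps_neighborhood(full_mask(4, 4), (4, 0), 1.0)

    def test_counts_grid_matches_per_pixel_queries(self, rng):
        mask = random_mask((15, 15), 0.5, seed=5)
        counts = _neighbor_counts(mask.values, 2.5)
        for p in [(0, 0), (7, 7), (14, 3), (2, 14)]:
            assert counts[p] == len(eps_neighborhood(mask, p, 2.5))


class TestDbscan:
    def test_empty_mask_yields_no_clusters(self):
        lm = dbscan(BinaryMask(np.zeros((6, 6), dtype=bool)), DbscanParams(1.5, 1))
        assert lm.n_clusters == 0
        assert np.all(lm.labels == BACKGROUND)

    def test_single_positive_pixel_minimal_core(self):
        values = np.zeros((5, 5), dtype=bool)
        values[2, 2] = True
        lm = dbscan(BinaryMask(values), DbscanParams(1.0, 1))
        assert lm.n_clusters == 1
        assert lm.labels[2, 2] == 1

    def test_sparse_block_below_minpxl_becomes_noise(self):
        # solid 10×10 square plus a distant 2×2 block: the block's best
        # neighborhood holds 4 < 5 pixels, so it is all noise
        mask = generate_binary_blobs(
            (30, 30), [("rect", (2, 2), (10, 10)), ("rect", (20, 20), (2, 2))]
        )
        lm = dbscan(mask, DbscanParams(1.5, 5))
        assert lm.n_clusters == 1
        block = lm.labels[20:22, 20:22]
        assert np.all(block == NOISE)
        assert np.all(lm.labels[2:12, 2:12] == 1)

    @pytest.mark.parametrize("seed", range(25))
    def test_partition_matches_bruteforce_closure(self, seed):
        local = np.random.default_rng(seed)
        h, w = local.integers(8, 41, size=2)
        density = local.uniform(0.15, 0.85)
        eps = local.choice([1.0, 1.5, 2.0, 3.0, 5.0])
        min_pxl = int(local.integers(1, 25))
        mask = random_mask((h, w), density, seed=seed + 1000)
        lm = dbscan(mask, DbscanParams(eps, min_pxl))
        assert_dbscan_matches_closure(lm, mask.values, eps, min_pxl)

    def test_partition_stable_under_geometric_transforms(self):
        mask = random_mask((30, 30), 0.5, seed=11)
        params = DbscanParams(2.0, 6)
        base = dbscan(mask, params).labels
        for transform in (np.flipud, np.fliplr, np.transpose):
            other = dbscan(BinaryMask(transform(mask.values)), params).labels
            back = transform(other)
            # pixel sets per cluster must agree modulo label renaming
            assert _same_partition(base, back)

    def test_core_set_monotone_in_minpxl(self):
        mask = random_mask((25, 25), 0.6, seed=3)
        counts = _neighbor_counts(mask.values, 2.0)
        for lo, hi in [(3, 6), (6, 12)]:
            core_lo = mask.values & (counts >= lo)
            core_hi = mask.values & (counts >= hi)
            assert np.all(core_lo | ~core_hi)  # core(hi) ⊆ core(lo)

    @pytest.mark.parametrize("eps", [np.sqrt(2), 1.5, 1.9])
    def test_minpxl_one_limit_equals_8_connected_components(self, eps):
        mask = random_mask((30, 30), 0.4, seed=17)
        lm = dbscan(mask, DbscanParams(eps, 1))
        comp, n = ndimage.label(mask.values, structure=np.ones((3, 3)))
        assert lm.n_clusters == n
        assert _same_partition(lm.labels, np.where(mask.values, comp, BACKGROUND))

    def test_deterministic_across_runs(self):
        mask = random_mask((40, 40), 0.5, seed=2)
        a = dbscan(mask, DbscanParams(2.5, 8))
        b = dbscan(mask, DbscanParams(2.5, 8))
        assert np.array_equal(a.labels, b.labels)


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """Cluster pixel-sets of two label grids agree up to ID renaming."""
    fwd, bwd = {}, {}
    for x, y in zip(a.ravel(), b.ravel()):
        if x <= 0 or y <= 0:
            if (x <= 0) != (y <= 0) or (x <= 0 and x != y):
                return False
            continue
        if fwd.setdefault(int(x), int(y)) != y or bwd.setdefault(int(y), int(x)) != x:
            return False
    return True


class TestExpandCluster:
    def test_failed_core_test_marks_seed_noise_only(self):
        values = np.zeros((10, 10), dtype=bool)
        values[2, 2] = values[2, 3] = values[7, 7] = True
        mask = BinaryMask(values)
        labels = np.where(values, UNCLASSIFIED, BACKGROUND).astype(np.int64)
        before = labels.copy()
        ok = expand_cluster(mask, labels, (2, 2), 1, DbscanParams(1.0, 3))
        assert not ok
        assert labels[2, 2] == NOISE
        changed = labels != before
        assert changed.sum() == 1 and changed[2, 2]

    def test_solid_disc_fully_labeled_from_any_interior_seed(self):
        mask = generate_binary_blobs((30, 30), [("disc", (15, 15), 10)])
        params = DbscanParams(1.5, 5)
        for seed in [(15, 15), (10, 12), (20, 18)]:
            labels = np.where(mask.values, UNCLASSIFIED, BACKGROUND).astype(np.int64)
            assert expand_cluster(mask, labels, seed, 1, params)
            assert np.all(labels[mask.values] == 1)

    def test_thin_bridge_matches_reference_closure(self):
        values = np.zeros((20, 40), dtype=bool)
        values[5:15, 2:12] = True  # blob A
        values[5:15, 28:38] = True  # blob B
        values[9, 12:28] = True  # 1-pixel bridge
        mask = BinaryMask(values)
        params = DbscanParams(1.5, 7)
        lm = dbscan(mask, params)
        assert_dbscan_matches_closure(lm, values, params.eps, params.min_pxl)

    def test_non_positive_seed_is_contract_violation(self):
        values = np.zeros((5, 5), dtype=bool)
        values[1, 1] = True
        labels = np.where(values, UNCLASSIFIED, BACKGROUND).astype(np.int64)
        with pytest.raises(ValueError):
            expand_cluster(BinaryMask(values), labels, (3, 3), 1, DbscanParams(1.0, 1))


class TestSelectLesionMask:
    def test_largest_cluster_selected_and_hole_filled(self):
        mask = generate_binary_blobs(
            (40, 40), [("rect", (5, 5), (12, 12)), ("rect", (25, 25), (5, 5))]
        )
        lm = dbscan(mask, DbscanParams(1.5, 4))
        assert lm.n_clusters == 2
        out = select_lesion_mask(lm, policy="largest")
        assert out.positive_count == 144
        assert np.all(out.values[5:17, 5:17])

    def test_annulus_cluster_filled_to_disc(self):
        outer = generate_binary_blobs((40, 40), [("disc", (20, 20), 12)]).values
        inner = generate_binary_blobs((40, 40), [("disc", (20, 20), 6)]).values
        ring = BinaryMask(outer & ~inner)
        lm = dbscan(ring, DbscanParams(1.5, 4))
        out = select_lesion_mask(lm)
        # oracle: flood-fill background from image border, complement
        free = ~ring.values
        comp, _ = ndimage.label(free, structure=ndimage.generate_binary_structure(2, 1))
        edge_ids = np.setdiff1d(
            np.unique(np.r_[comp[0], comp[-1], comp[:, 0], comp[:, -1]]), [0]
        )
        expected = ~np.isin(comp, edge_ids) | ring.values
        assert np.array_equal(out.values, expected)

    def test_policy_all_returns_union(self):
        mask = generate_binary_blobs(
            (40, 40), [("rect", (5, 5), (8, 8)), ("rect", (25, 25), (8, 8))]
        )
        lm = dbscan(mask, DbscanParams(1.5, 4))
        out = select_lesion_mask(lm, policy="all", fill_holes=False)
        assert out == mask

    def test_empty_clustering_warns_and_returns_empty(self):
        lm = dbscan(BinaryMask(np.zeros((5, 5), dtype=bool)), DbscanParams(1.0, 1))
        with pytest.warns(UserWarning):
            out = select_lesion_mask(lm)
        assert out.positive_count == 0
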