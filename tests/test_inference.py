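"""Group t-maps, cluster labeling, block permutation, corrected thresholds."""

import numpy as np
import pytest
from scipy import stats

import infoconn as icn
from infoconn.inference import (
    Cluster,
    NullDistribution,
    max_cluster_size,
)


# ---------------------------------------------------------------------------
# group t-test
# ---------------------------------------------------------------------------

def test_one_sample_t_closed_form():
    vals = np.array([1.0, 2, 3, 4, 5])
    maps = [np.full((2, 2, 2), v) for v in vals]
    t, p = icn.group_ttest(maps)
    expected_t = vals.mean() / (vals.std(ddof=1) / np.sqrt(5))
    assert t[0, 0, 0] == pytest.approx(expected_t)
    assert p[0, 0, 0] == pytest.approx(stats.t.sf(expected_t, df=4))


def test_symmetric_values_give_t_zero_p_half():
    maps = [np.full((2, 2, 2), v) for v in (-2.0, -1.0, 0.0, 1.0, 2.0)]
    t, p = icn.group_ttest(maps)
    assert t[0, 0, 0] == pytest.approx(0.0)
    assert p[0, 0, 0] == pytest.approx(0.5)


def test_zero_variance_voxels_flagged_p_one():
    maps = [np.full((2, 2, 2), 3.0) for _ in range(4)]
    t, p = icn.group_ttest(maps)
    assert np.all(t == 0) and np.all(p == 1)


def test_group_t_matches_scipy_oracle():
    rng = np.random.default_rng(21)
    stack = rng.normal(size=(6, 3, 3, 3))
    t, p = icn.group_ttest(list(stack))
    ref = stats.ttest_1samp(stack, 0.0, axis=0, alternative="greater")
    assert np.allclose(t, ref.statistic, atol=1e-10)
    assert np.allclose(p, ref.pvalue, atol=1e-10)


# ---------------------------------------------------------------------------
# cluster labeling
# ---------------------------------------------------------------------------

def flood_fill_clusters(binary, connectivity=6):
    """Brute-force BFS component labeling oracle."""
    binary = np.asarray(binary, bool)
    if connectivity == 6:
        neigh = [o for o in np.ndindex(3, 3, 3)
                 if sum(abs(np.array(o) - 1)) == 1]
    else:
        neigh = [o for o in np.ndindex(3, 3, 3) if tuple(o) != (1, 1, 1)]
    offsets = [np.array(o) - 1 for o in neigh]
    seen = np.zeros(binary.shape, bool)
    comps = []
    for start in np.argwhere(binary):
        if seen[tuple(start)]:
            continue
        queue, comp = [tuple(start)], set()
        seen[tuple(start)] = True
        while queue:
            cur = queue.pop()
            comp.add(cur)
            for off in offsets:
                nb = tuple(np.array(cur) + off)
                if all(0 <= c < s for c, s in zip(nb, binary.shape)) \
                        and binary[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


def test_opposite_corners_are_two_singletons():
    b = np.zeros((4, 4, 4), bool)
    b[0, 0, 0] = b[3, 3, 3] = True
    _, sizes = icn.label_clusters(b)
    assert sorted(sizes) == [1, 1]


def test_solid_block_is_one_cluster():
    b = np.zeros((5, 5, 5), bool)
    b[1:3, 1:3, 1:3] = True
    _, sizes = icn.label_clusters(b)
    assert sizes.tolist() == [8]


@pytest.mark.parametrize("connectivity", [6, 26])
def test_random_map_matches_flood_fill_oracle(connectivity):
    rng = np.random.default_rng(22)
    b = rng.random((8, 8, 8)) > 0.7
    labels, sizes = icn.label_clusters(b, connectivity)
    got = set()
    for lab in range(1, len(sizes) + 1):
        got.add(frozenset(map(tuple, np.argwhere(labels == lab))))
    assert got == flood_fill_clusters(b, connectivity)


def test_diagonal_voxels_connectivity_dependent():
    b = np.zeros((3, 3, 3), bool)
    b[0, 0, 0] = b[1, 1, 1] = True
    assert max_cluster_size(b, 6) == 1
    assert max_cluster_size(b, 26) == 2


def test_bad_connectivity_rejected():
    with pytest.raises(ValueError, match="connectivity"):
        icn.label_clusters(np.ones((2, 2, 2), bool), 10)


# ---------------------------------------------------------------------------
# block permutation
# ---------------------------------------------------------------------------

def blocked_series(n_blocks=3, block_len=3):
    values = np.arange(n_blocks * block_len, dtype=float)
    blocks = np.repeat(np.arange(n_blocks), block_len)
    return values, blocks


def test_permutation_preserves_multiset_and_block_order():
    values, blocks = blocked_series(4, 3)
    rng = np.random.default_rng(23)
    for _ in range(20):
        out = icn.permute_seed_series(values, blocks, rng)
        assert sorted(out) == sorted(values)
        # within-block ascending order preserved (values were ascending)
        for b in range(4):
            seg = out[blocks == b]
            assert np.all(np.diff(seg) == 1)


def test_unlabeled_entries_rejected():
    values = np.arange(4.0)
    with pytest.raises(ValueError, match="belong to a block"):
        icn.permute_seed_series(values, np.array([0, 0, -1, 1]), np.random.default_rng(0))


def test_three_equal_blocks_uniform_over_six_orderings():
    values, blocks = blocked_series(3, 2)
    rng = np.random.default_rng(24)
    counts = {}
    n_draws = 1200
    for _ in range(n_draws):
        out = icn.permute_seed_series(values, blocks, rng)
        key = tuple(int(out[blocks == b][0] // 2) for b in range(3))
        counts[key] = counts.get(key, 0) + 1
    assert len(counts) == 6
    chi = stats.chisquare(list(counts.values()))
    assert chi.pvalue > 1e-3


def test_unequal_block_lengths_swap_within_matching_groups():
    values = np.array([0.0, 1, 2, 3, 4, 5, 6])
    blocks = np.array([0, 0, 1, 1, 1, 2, 2])  # lengths 2, 3, 2
    rng = np.random.default_rng(25)
    for _ in range(20):
        out = icn.permute_seed_series(values, blocks, rng)
        # the unique length-3 block can only map to itself
        assert np.array_equal(out[2:5], values[2:5])
        assert sorted(out) == sorted(values)


def test_within_run_constraint_respected():
    values = np.arange(8.0)
    blocks = np.repeat([0, 1, 2, 3], 2)
    runs = np.repeat([0, 0, 1, 1], 2)
    rng = np.random.default_rng(26)
    for _ in range(20):
        out = icn.permute_seed_series(values, blocks, rng, run_of_entry=runs)
        assert set(out[:4]) == {0, 1, 2, 3}
        assert set(out[4:]) == {4, 5, 6, 7}


# ---------------------------------------------------------------------------
# null distribution and correction
# ---------------------------------------------------------------------------

def test_corrected_min_cluster_hand_ordered():
    null = NullDistribution(np.array([10, 9, 8, 7, 6, 5, 4, 3, 2, 1]),
                            n_group_maps=10, n_subject_perms=1)
    assert icn.corrected_min_cluster(null, alpha=0.2) == 9
    assert icn.corrected_min_cluster(null, alpha=0.5) == 6


def test_corrected_min_cluster_is_kth_largest_at_alpha_05():
    rng = np.random.default_rng(27)
    sizes = rng.permutation(np.arange(1, 1001))
    null = NullDistribution(sizes, n_group_maps=1000, n_subject_perms=100)
    # 50th largest of 1..1000 is 951
    assert icn.corrected_min_cluster(null, alpha=0.05) == 951


def test_corrected_min_cluster_monotone_in_alpha():
    rng = np.random.default_rng(28)
    null = NullDistribution(rng.integers(0, 40, 200), 200, 10)
    thresholds = [icn.corrected_min_cluster(null, a) for a in (0.05, 0.1, 0.2, 0.5)]
    assert thresholds == sorted(thresholds, reverse=True)


def test_alpha_bounds_rejected():
    null = NullDistribution(np.arange(10), 10, 1)
    with pytest.raises(ValueError):
        icn.corrected_min_cluster(null, alpha=0.0)
    with pytest.raises(ValueError, match="too small"):
        icn.corrected_min_cluster(null, alpha=0.01)


def test_apply_correction_planted_blob():
    t = np.zeros((8, 8, 8))
    p = np.ones((8, 8, 8))
    blob = [(2, 2, 2), (2, 2, 3), (2, 3, 2), (3, 2, 2), (2, 3, 3), (3, 3, 2)]
    for v in blob:
        t[v], p[v] = 5.0, 1e-5
    mask = np.ones((8, 8, 8), bool)
    res = icn.apply_correction(t, p, mask, 0.001, min_cluster_size=5, n_subjects=5)
    assert len(res.clusters) == 1
    assert res.clusters[0].size_voxels == 6
    assert res.clusters[0].peak_t == 5.0
    # strict inequality at the boundary: a 5-voxel blob is excluded
    res5 = icn.apply_correction(t, p, mask, 0.001, min_cluster_size=6, n_subjects=5)
    assert res5.clusters == []


def test_apply_correction_empty_when_nothing_survives():
    shape = (5, 5, 5)
    res = icn.apply_correction(
        np.zeros(shape), np.ones(shape), np.ones(shape, bool), 0.001, 3, 4
    )
    assert res.clusters == [] and not res.significant_mask.any()


def test_build_null_deterministic_and_nonnegative():
    rng_maps = np.random.default_rng(29)
    base = [rng_maps.normal(size=(6, 6, 6)) for _ in range(4)]

    def pipeline(subj, rng):
        return subj + rng.normal(scale=0.5, size=subj.shape)

    mask = np.ones((6, 6, 6), bool)
    null1 = icn.build_null(base, pipeline, mask, n_subject_perms=10,
                           n_group_maps=30, threshold_p=0.05, rng=7)
    null2 = icn.build_null(base, pipeline, mask, n_subject_perms=10,
                           n_group_maps=30, threshold_p=0.05, rng=7)
    assert np.array_equal(null1.max_cluster_sizes, null2.max_cluster_sizes)
    assert null1.rng_seed == 7
    assert (null1.max_cluster_sizes >= 0).all()
    assert len(null1.max_cluster_sizes) == 30


def test_group_result_rejects_undersized_cluster():
    c = Cluster(size_voxels=2, peak_t=1.0, peak_voxel=(0, 0, 0),
                center_voxel=(0, 0, 0), members=np.array([[0, 0, 0], [0, 0, 1]]))
    with pytest.raises(ValueError, match="below the minimum"):
        icn.GroupResult(
            t_map=np.zeros((2, 2, 2)), p_map=np.ones((2, 2, 2)),
            threshold_p=0.001, min_cluster_size=5, clusters=[c], n_subjects=3,
        )
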