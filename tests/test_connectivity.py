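"""IC/FC maps, Spearman, Fisher transform, mask-aware smoothing."""

import numpy as np
import pytest
from scipy import stats

import infoconn as icn
from infoconn.connectivity import ConnectivityMap, partial_correlation

from conftest import make_dataset


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def test_spearman_identity_and_monotone_invariance():
    a = np.array([0.3, 1.2, -0.5, 2.0, 0.9])
    assert icn.spearman(a, a) == pytest.approx(1.0)
    assert icn.spearman(a, np.exp(a)) == pytest.approx(1.0)
    assert icn.spearman(a, -a) == pytest.approx(-1.0)


def test_spearman_small_example():
    assert icn.spearman(np.array([1.0, 2, 3]), np.array([10.0, 20, 15])) == pytest.approx(0.5)


def test_spearman_with_ties_matches_scipy():
    a = np.array([1.0, 2, 2, 3, 5, 5, 5, 8])
    b = np.array([4.0, 4, 1, 7, 2, 9, 9, 3])
    assert icn.spearman(a, b) == pytest.approx(stats.spearmanr(a, b).statistic, abs=1e-12)


def test_spearman_degenerate_series_is_zero():
    assert icn.spearman(np.ones(5), np.arange(5.0)) == 0.0


def test_spearman_short_input_errors():
    with pytest.raises(ValueError, match="at least 3"):
        icn.spearman(np.array([1.0, 2]), np.array([3.0, 4]))


# ---------------------------------------------------------------------------
# IC maps
# ---------------------------------------------------------------------------

def test_ic_map_is_one_at_seed_center(tiny_preprocessed, tiny_spec):
    ds, labels = tiny_preprocessed
    seed = icn.build_sphere((5, 5, 5), 2.0, ds.mask)
    cmap = icn.ic_map(ds, seed, labels, tiny_spec.conditions, radius_vox=2.0)
    assert cmap.values[5, 5, 5] == pytest.approx(1.0, abs=1e-9)
    assert cmap.method == "IC"
    assert cmap.seed["n_members"] == seed.n_members


def test_ic_values_are_spearman_of_series(tiny_preprocessed, tiny_spec):
    ds, labels = tiny_preprocessed
    conds = tiny_spec.conditions
    seed = tiny_spec.regions[0].voxels
    seed_series = icn.discriminability_timeseries(ds, seed, labels, conds)
    cmap = icn.ic_map(ds, seed, labels, conds, radius_vox=2.0)
    other = tuple(tiny_spec.regions[1].voxels.center)
    target = icn.discriminability_timeseries(
        ds, icn.build_sphere(other, 2.0, ds.mask), labels, conds
    )
    assert cmap.values[other] == pytest.approx(
        icn.spearman(seed_series.values, target.values), abs=1e-12
    )


def test_coupled_region_scores_higher_than_far_noise(tiny_preprocessed, tiny_spec):
    ds, labels = tiny_preprocessed
    seed = tiny_spec.regions[0].voxels
    cmap = icn.ic_map(ds, seed, labels, tiny_spec.conditions, radius_vox=2.0)
    coupled = cmap.values[tuple(tiny_spec.regions[1].voxels.center)]
    noise_center = (3, 8, 3)  # outside both regions
    assert coupled > cmap.values[noise_center] + 0.1


# ---------------------------------------------------------------------------
# FC maps and partial correlation
# ---------------------------------------------------------------------------

def test_partial_correlation_matches_two_stage_ols_oracle():
    rng = np.random.default_rng(11)
    n = 40
    cov = rng.normal(size=(n, 2))
    seed = rng.normal(size=n)
    target = 0.5 * seed + cov @ [1.0, -2.0] + rng.normal(size=n)
    got = partial_correlation(seed, target[None, :], cov)[0]
    design = np.column_stack([np.ones(n), cov])
    rs = seed - design @ np.linalg.lstsq(design, seed, rcond=None)[0]
    rt = target - design @ np.linalg.lstsq(design, target, rcond=None)[0]
    assert got == pytest.approx(stats.pearsonr(rs, rt)[0], abs=1e-10)


def test_fc_map_self_voxel_is_one(tiny_preprocessed, tiny_spec):
    ds, labels = tiny_preprocessed
    vox = (2, 9, 2)
    seed = icn.VoxelSet(center=vox, radius_vox=0, members=[vox])
    cmap = icn.fc_map(ds, seed, None, labels, tiny_spec.conditions)
    assert cmap.values[vox] == pytest.approx(1.0)
    assert cmap.method == "FC"


def test_fc_target_equal_to_covariate_partialled_out(tiny_preprocessed, tiny_spec):
    ds, labels = tiny_preprocessed
    trs = icn.select_condition_trs(labels, tiny_spec.conditions)
    vox = (2, 9, 2)
    cov_series = ds.data[vox]  # make the covariate exactly this voxel
    nuisance = icn.NuisanceSet(cov_series[:, None], ["v"])
    seed = icn.VoxelSet(center=(9, 2, 2), radius_vox=0, members=[(9, 2, 2)])
    cmap = icn.fc_map(ds, seed, nuisance, labels, tiny_spec.conditions)
    assert abs(cmap.values[vox]) < 1e-8


def test_fc_searchlight_granularity_targets_mean_series(tiny_preprocessed, tiny_spec):
    ds, labels = tiny_preprocessed
    seed = tiny_spec.regions[0].voxels
    cmap = icn.fc_map(
        ds, seed, None, labels, tiny_spec.conditions,
        granularity="searchlight", radius_vox=2.0,
    )
    # oracle at one center: partial corr of seed mean with sphere-mean series
    trs = icn.select_condition_trs(labels, tiny_spec.conditions)
    seed_series = ds.data[tuple(seed.members.T)][:, trs].mean(axis=0)
    center = (8, 3, 8)
    sphere = icn.build_sphere(center, 2.0, ds.mask)
    target = ds.data[tuple(sphere.members.T)][:, trs].mean(axis=0)
    assert cmap.values[center] == pytest.approx(
        stats.pearsonr(seed_series, target)[0], abs=1e-10
    )


# ---------------------------------------------------------------------------
# Fisher transform and smoothing
# ---------------------------------------------------------------------------

def _flat_map(values, mask=None):
    values = np.asarray(values, float)
    if mask is None:
        mask = np.ones(values.shape, bool)
    return ConnectivityMap(values=values, mask=mask, method="IC", seed={})


def test_fisher_map_closed_form():
    cmap = _flat_map(np.full((3, 3, 3), 0.5))
    out = icn.fisher_map(cmap)
    assert out.values[0, 0, 0] == pytest.approx(0.5 * np.log(3.0))
    assert out.fisher_transformed
    zero = icn.fisher_map(_flat_map(np.zeros((2, 2, 2))))
    assert np.allclose(zero.values, 0.0)


def test_fisher_double_transform_rejected():
    out = icn.fisher_map(_flat_map(np.zeros((2, 2, 2))))
    with pytest.raises(ValueError, match="already"):
        icn.fisher_map(out)


def test_fisher_preserves_order():
    rng = np.random.default_rng(12)
    vals = rng.uniform(-0.9, 0.9, size=(4, 4, 4))
    out = icn.fisher_map(_flat_map(vals))
    a, b = vals.ravel(), out.values.ravel()
    assert np.array_equal(np.argsort(a), np.argsort(b))


def test_smooth_fwhm_zero_is_identity():
    rng = np.random.default_rng(13)
    cmap = _flat_map(rng.normal(size=(5, 5, 5)))
    out = icn.smooth_map(cmap, 0.0, np.ones(3))
    assert np.array_equal(out.values, cmap.values)


def test_smooth_constant_map_unchanged_inside_irregular_mask():
    rng = np.random.default_rng(14)
    mask = rng.random((7, 7, 7)) > 0.4
    cmap = _flat_map(np.where(mask, 2.5, 0.0), mask)
    out = icn.smooth_map(cmap, 6.0, np.ones(3))
    assert np.allclose(out.values[mask], 2.5, atol=1e-10)
    assert np.all(out.values[~mask] == 0)


def test_smooth_delta_matches_direct_convolution_oracle():
    mask = np.ones((7, 7, 7), dtype=bool)
    mask[:, :2, :] = False  # asymmetric support
    vals = np.zeros((7, 7, 7))
    vals[3, 3, 3] = 1.0
    fwhm, voxel = 2.0, np.array([1.0, 1.0, 1.0])
    out = icn.smooth_map(_flat_map(vals, mask), fwhm, voxel)
    sigma = (fwhm / voxel) / (2 * np.sqrt(2 * np.log(2)))
    grid = np.stack(np.meshgrid(*[np.arange(7)] * 3, indexing="ij"), -1)
    for probe in [(3, 3, 3), (2, 4, 3), (3, 2, 5)]:
        d2 = (((grid - np.array(probe)) / sigma) ** 2).sum(-1)
        w = np.exp(-0.5 * d2) * mask
        expected = (w * vals).sum() / w.sum()
        assert out.values[probe] == pytest.approx(expected, abs=1e-4)


def test_smoothing_metadata_recorded(tiny_preprocessed, tiny_spec):
    ds, labels = tiny_preprocessed
    seed = tiny_spec.regions[0].voxels
    cmap = icn.ic_map(ds, seed, labels, tiny_spec.conditions, radius_vox=2.0)
    out = icn.smooth_map(icn.fisher_map(cmap), 8.0, ds.voxel_size_mm)
    assert out.smoothed_fwhm_mm == 8.0 and out.fisher_transformed


# ---------------------------------------------------------------------------
# searchlight characterization
# ---------------------------------------------------------------------------

def test_characterization_table(tiny_preprocessed, tiny_spec):
    ds, labels = tiny_preprocessed
    conds = tiny_spec.conditions
    seed = tiny_spec.regions[0].voxels
    cmap = icn.ic_map(ds, seed, labels, conds, radius_vox=2.0)
    table = icn.characterize_searchlights(ds, labels, conds, 2.0, [cmap], seed=seed)
    assert {"mean_activation", "accuracy", "IC", "overlaps_seed"} <= set(table.columns)
    assert len(table) == int(ds.mask.sum())
    # overlap flag: seed's own center definitely overlaps
    row = table[(table.i == 3) & (table.j == 3) & (table.k == 3)].iloc[0]
    assert bool(row.overlaps_seed)
    # mean activation oracle at one center
    trs = icn.select_condition_trs(labels, conds)
    sphere = icn.build_sphere((8, 8, 8), 2.0, ds.mask)
    expected = ds.data[tuple(sphere.members.T)][:, trs].mean()
    got = table[(table.i == 8) & (table.j == 8) & (table.k == 8)].iloc[0].mean_activation
    assert got == pytest.approx(expected, abs=1e-10)
    # accuracy column within [0, 1] and IC column matches the map
    assert table.accuracy.between(0, 1).all()
    assert table.IC.iloc[0] == cmap.values[tuple(table[["i", "j", "k"]].iloc[0])]
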