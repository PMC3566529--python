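"""End-to-end seed analyses: per-subject map construction with a cached
searchlight sweep, block-permutation map resampling, and group-level
cluster-corrected inference for both IC and FC.

The expensive object per subject is the whole-brain searchlight
discriminability matrix (IC) or the covariate-residualized target matrix
(FC); both are computed once and reused across the hundred block
permutations of the seed series, each permuted map passing through the
identical Fisher-transform + smoothing pipeline as the real map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMap, fisher_map, smooth_map
from .discriminability import (
    discriminability_timeseries,
    searchlight_discriminability,
)
from .inference import (
    GroupResult,
    NullDistribution,
    apply_correction,
    build_null,
    corrected_min_cluster,
    group_ttest,
    permute_seed_series,
)
from .io_preproc import (
    BoldDataset,
    LabelTimeline,
    NuisanceSet,
    preprocess,
    select_condition_trs,
)
from .searchlight import VoxelSet, build_sphere


@dataclass
class SeedSubject:
    """One subject's cached state for seed-based connectivity.

    Holds everything needed to produce the real map and any number of
    block-permuted maps without re-running the searchlight sweep.
    """

    method: str  # "IC" or "FC"
    seed_values: np.ndarray  # seed series over analyzed TRs
    block_of_entry: np.ndarray
    run_of_entry: np.ndarray
    mask: np.ndarray
    voxel_size_mm: np.ndarray
    fwhm_mm: float
    subject: str | None = None
    sl_disc: object | None = None  # SearchlightDiscriminability (IC)
    fc_targets: np.ndarray | None = None  # residualized targets (FC)
    fc_covariates: np.ndarray | None = None
    #: Mask used for smoothing and group inference.  When seed-overlap
    #: exclusion is on, this is the brain mask minus targets that contain
    #: the seed's own voxels; excluding them *before* smoothing keeps the
    #: seed's trivial self-correlation from leaking into neighbours.
    analysis_mask: np.ndarray | None = None

    # permutations only re-rank / re-residualize the seed series, so the
    # target side (searchlight ranks, residualized voxel series) is cached
    _ic_target_zranks: np.ndarray | None = None
    _fc_design_q: np.ndarray | None = None
    _fc_target_z: np.ndarray | None = None

    def _target_cache(self):
        from scipy.stats import rankdata

        from .connectivity import _standardize_rows

        if self.method == "IC":
            if self._ic_target_zranks is None:
                self._ic_target_zranks = _standardize_rows(
                    rankdata(self.sl_disc.values, axis=1)
                )
            return self._ic_target_zranks
        if self._fc_target_z is None:
            n = self.fc_targets.shape[1]
            design = np.ones((n, 1))
            if self.fc_covariates is not None and np.size(self.fc_covariates):
                design = np.column_stack([design, self.fc_covariates])
            self._fc_design_q, _ = np.linalg.qr(design)
            q = self._fc_design_q
            self._fc_target_z = _standardize_rows(
                self.fc_targets - (self.fc_targets @ q) @ q.T
            )
        return self._fc_target_z

    def _raw_values(self, seed_values: np.ndarray) -> np.ndarray:
        """Seed-to-target correlations (one per searchlight center / voxel)."""
        from scipy.stats import rankdata

        from .connectivity import _standardize_rows

        zt = self._target_cache()
        n = len(seed_values)
        if self.method == "IC":
            zs = _standardize_rows(rankdata(seed_values)[None, :])[0]
        else:
            q = self._fc_design_q
            resid = seed_values - q @ (q.T @ seed_values)
            zs = _standardize_rows(resid[None, :])[0]
        return np.clip(zt @ zs / n, -1.0, 1.0)

    def _raw_map(self, seed_values: np.ndarray) -> ConnectivityMap:
        r = self._raw_values(seed_values)
        if self.method == "IC":
            return ConnectivityMap(
                values=self.sl_disc.index.map_to_volume(r),
                mask=self.mask,
                method="IC",
                seed={},
                subject=self.subject,
            )
        values = np.zeros(self.mask.shape)
        values[self.mask] = r
        return ConnectivityMap(
            values=values, mask=self.mask, method="FC", seed={}, subject=self.subject
        )

    def processed_map(self, seed_values: np.ndarray | None = None) -> ConnectivityMap:
        """Fisher-transformed, smoothed map for the given (or real) seed series."""
        if seed_values is None:
            seed_values = self.seed_values
        raw = self._raw_map(np.asarray(seed_values, dtype=np.float64))
        if self.analysis_mask is not None:
            values = np.where(self.analysis_mask, raw.values, 0.0)
            raw = ConnectivityMap(
                values=values, mask=self.analysis_mask, method=raw.method,
                seed=raw.seed, subject=raw.subject,
            )
        return smooth_map(fisher_map(raw), self.fwhm_mm, self.voxel_size_mm)

    def permuted_map(self, rng: np.random.Generator) -> np.ndarray:
        """One block-permuted, fully processed map (values array)."""
        perm = permute_seed_series(self.seed_values, self.block_of_entry, rng)
        return self.processed_map(perm).values


def prepare_subject_ic(
    dataset: BoldDataset,
    labels: LabelTimeline,
    seed: VoxelSet,
    conditions,
    radius_vox: float = 3.0,
    fwhm_mm: float = 8.0,
    subject: str | None = None,
    exclude_seed_overlap: bool = True,
) -> SeedSubject:
    """Compute the seed discriminability series and the whole-brain
    searchlight sweep for one (already preprocessed) subject.

    With ``exclude_seed_overlap`` (default) searchlight centers whose
    sphere shares voxels with the seed are removed from the analysis mask
    before smoothing — they correlate with the seed trivially.
    """
    seed_series = discriminability_timeseries(dataset, seed, labels, conditions)
    sl = searchlight_discriminability(dataset, labels, conditions, radius_vox)
    trs = seed_series.tr_index
    analysis_mask = None
    if exclude_seed_overlap:
        analysis_mask = dataset.mask.copy()
        overlap = sl.index.overlaps(seed)
        analysis_mask[tuple(sl.index.centers[overlap].T)] = False
    return SeedSubject(
        method="IC",
        seed_values=seed_series.values,
        block_of_entry=labels.block_of_tr[trs],
        run_of_entry=labels.run_of_tr[trs],
        mask=dataset.mask,
        voxel_size_mm=dataset.voxel_size_mm,
        fwhm_mm=fwhm_mm,
        subject=subject,
        sl_disc=sl,
        analysis_mask=analysis_mask,
    )


def prepare_subject_fc(
    dataset: BoldDataset,
    labels: LabelTimeline,
    seed: VoxelSet,
    conditions,
    nuisance: NuisanceSet | None = None,
    fwhm_mm: float = 8.0,
    subject: str | None = None,
    exclude_seed_overlap: bool = True,
) -> SeedSubject:
    """Cache the seed mean series and voxel target matrix for FC.

    With ``exclude_seed_overlap`` the seed's own voxels (which compose the
    seed mean and so correlate with it trivially) are removed from the
    analysis mask before smoothing.
    """
    trs = select_condition_trs(labels, conditions)
    x = dataset.masked_timeseries()[:, trs]
    seed_idx = np.flatnonzero(seed.indicator(dataset.spatial_shape)[dataset.mask])
    seed_series = x[seed_idx].mean(axis=0)
    cov = nuisance.regressors[trs] if nuisance is not None else None
    analysis_mask = None
    if exclude_seed_overlap:
        analysis_mask = dataset.mask & ~seed.indicator(dataset.spatial_shape)
    return SeedSubject(
        method="FC",
        seed_values=seed_series,
        block_of_entry=labels.block_of_tr[trs],
        run_of_entry=labels.run_of_tr[trs],
        mask=dataset.mask,
        voxel_size_mm=dataset.voxel_size_mm,
        fwhm_mm=fwhm_mm,
        subject=subject,
        fc_targets=x,
        fc_covariates=cov,
        analysis_mask=analysis_mask,
    )


@dataclass
class SeedGroupAnalysis:
    """Group inference bundle: real result, null distribution, threshold."""

    result: GroupResult
    null: NullDistribution
    min_cluster_size: int
    subject_maps: list


def group_analysis(
    subjects: list[SeedSubject],
    threshold_p: float = 0.001,
    alpha: float = 0.05,
    n_subject_perms: int = 100,
    n_group_maps: int = 1000,
    connectivity: int = 6,
    rng: np.random.Generator | int | None = None,
    analysis_mask: np.ndarray | None = None,
) -> SeedGroupAnalysis:
    """Real group map plus block-permutation cluster correction.

    ``analysis_mask`` restricts cluster detection (e.g. to exclude
    searchlights overlapping the seed, which correlate with it trivially);
    it defaults to the full brain mask.
    """
    if analysis_mask is not None:
        mask = np.asarray(analysis_mask, bool)
    elif subjects[0].analysis_mask is not None:
        mask = subjects[0].analysis_mask
    else:
        mask = subjects[0].mask
    real_maps = [s.processed_map() for s in subjects]
    t, p = group_ttest(real_maps, mask=mask)
    null = build_null(
        subjects,
        pipeline=lambda subj, r: subj.permuted_map(r),
        mask=mask,
        n_subject_perms=n_subject_perms,
        n_group_maps=n_group_maps,
        threshold_p=threshold_p,
        connectivity=connectivity,
        rng=rng,
    )
    min_size = corrected_min_cluster(null, alpha)
    result = apply_correction(
        t, p, mask, threshold_p, min_size, n_subjects=len(subjects),
        connectivity=connectivity,
    )
    return SeedGroupAnalysis(
        result=result, null=null, min_cluster_size=min_size, subject_maps=real_maps
    )


def preprocess_subject(
    dataset: BoldDataset,
    labels: LabelTimeline,
    nuisance: NuisanceSet | None,
    detrend_order: int = 2,
    shift_trs: int = 2,
) -> tuple[BoldDataset, LabelTimeline]:
    """Convenience wrapper over :func:`infoconn.io_preproc.preprocess`."""
    return preprocess(dataset, labels, nuisance, detrend_order, shift_trs)


def seed_from_spec(center, radius_vox: float, mask: np.ndarray) -> VoxelSet:
    """Build a spherical seed from (center, radius), truncated to the mask."""
    return build_sphere(tuple(center), radius_vox, mask)
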