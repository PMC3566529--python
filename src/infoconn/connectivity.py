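"""Seed-based informational-connectivity (IC) and functional-connectivity
(FC) maps.

IC correlates (Spearman) a seed region's discriminability timeseries with
the discriminability timeseries of every searchlight; the rank correlation
is placed at each searchlight's central voxel.  FC is the matched
univariate baseline: the seed's mean activation timeseries over the same
TRs, related to every voxel (or searchlight-mean) timeseries as a partial
correlation given nuisance covariates.  Per-subject maps are
Fisher-transformed and spatially smoothed (mask-aware Gaussian) before
group inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.stats import rankdata

from .discriminability import (
    SearchlightDiscriminability,
    discriminability_timeseries,
    fisher_z,
    searchlight_discriminability,
)
from .io_preproc import BoldDataset, LabelTimeline, NuisanceSet, select_condition_trs
from .searchlight import SearchlightIndex, VoxelSet

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class ConnectivityMap:
    """3D map of seed-to-searchlight (or seed-to-voxel) association values.

    Values are defined on the mask (searchlight centers); voxels outside
    the mask are zero-filled and carry no meaning.
    """

    values: np.ndarray
    mask: np.ndarray
    method: str  # "IC" or "FC"
    seed: dict
    subject: str | None = None
    fisher_transformed: bool = False
    smoothed_fwhm_mm: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite map values inside mask")

    def save(self, path, affine: np.ndarray | None = None) -> None:
        """Write the map as NIfTI-1 plus a JSON sidecar with provenance."""
        img = nib.Nifti1Image(
            self.values.astype(np.float32),
            affine if affine is not None else np.eye(4),
        )
        nib.save(img, str(path))
        sidecar = {
            "method": self.method,
            "seed": self.seed,
            "subject": self.subject,
            "fisher_transformed": self.fisher_transformed,
            "smoothed_fwhm_mm": self.smoothed_fwhm_mm,
        }
        with open(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


# ---------------------------------------------------------------------------
# rank correlation
# ---------------------------------------------------------------------------

def spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation: Pearson of average-ranked values.

    Ties receive average ranks; a series with no rank variation yields 0.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if len(a) < 3:
        raise ValueError("need at least 3 observations")
    ra = rankdata(a)
    rb = rankdata(b)
    sa = ra.std()
    sb = rb.std()
    if sa < 1e-12 or sb < 1e-12:
        return 0.0
    return float(np.clip(np.corrcoef(ra, rb)[0, 1], -1.0, 1.0))


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Z-score rows (population sd); zero-variance rows become all-zero."""
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    out = (x - mu) / np.where(sd > 1e-12, sd, 1.0)
    out[np.broadcast_to(sd <= 1e-12, out.shape)] = 0.0
    return out


def spearman_map_values(
    seed_values: np.ndarray, searchlight_values: np.ndarray
) -> np.ndarray:
    """Spearman r of one seed series against each row of a series matrix."""
    zr_sl = _standardize_rows(rankdata(searchlight_values, axis=1))
    zr_seed = _standardize_rows(rankdata(seed_values))
    return np.clip(zr_sl @ zr_seed / len(seed_values), -1.0, 1.0)


# ---------------------------------------------------------------------------
# IC
# ---------------------------------------------------------------------------

def ic_map(
    dataset: BoldDataset,
    seed: VoxelSet,
    labels: LabelTimeline,
    conditions,
    radius_vox: float = 3.0,
    sl_disc: SearchlightDiscriminability | None = None,
    subject: str | None = None,
) -> ConnectivityMap:
    """Informational-connectivity map for one subject.

    The seed's discriminability series is rank-correlated with every
    searchlight's series; each r_s lands at the searchlight's center voxel.
    A precomputed :class:`SearchlightDiscriminability` may be passed to
    reuse the expensive whole-brain sweep (e.g. across permutations).
    """
    seed_series = discriminability_timeseries(dataset, seed, labels, conditions)
    if sl_disc is None:
        sl_disc = searchlight_discriminability(dataset, labels, conditions, radius_vox)
    return ic_map_from_series(
        seed_series.values, sl_disc, seed_meta=_seed_meta(seed), subject=subject
    )


def ic_map_from_series(
    seed_values: np.ndarray,
    sl_disc: SearchlightDiscriminability,
    seed_meta: dict | None = None,
    subject: str | None = None,
) -> ConnectivityMap:
    """IC map from an explicit seed discriminability series (permutation path)."""
    if len(seed_values) != sl_disc.values.shape[1]:
        raise ValueError("seed series length must match searchlight trial count")
    rs = spearman_map_values(np.asarray(seed_values, dtype=np.float64), sl_disc.values)
    return ConnectivityMap(
        values=sl_disc.index.map_to_volume(rs),
        mask=sl_disc.index.mask,
        method="IC",
        seed=seed_meta or {},
        subject=subject,
    )


def _seed_meta(seed: VoxelSet) -> dict:
    return {
        "center": list(seed.center),
        "radius_vox": seed.radius_vox,
        "n_members": seed.n_members,
    }


# ---------------------------------------------------------------------------
# FC
# ---------------------------------------------------------------------------

def partial_correlation(
    seed: np.ndarray, targets: np.ndarray, covariates: np.ndarray | None
) -> np.ndarray:
    """Partial correlation of a seed series with each target row, given
    covariates.

    Both sides are residualized on [intercept, covariates] and the
    residuals correlated; equivalent to the normalized GLM fit of each
    target on the seed with the covariates in the model.  Degenerate
    (zero-residual-variance) targets yield 0.
    """
    seed = np.asarray(seed, dtype=np.float64)
    targets = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    n = len(seed)
    design = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        design = np.column_stack([design, covariates])
    q, _ = np.linalg.qr(design)
    rs_seed = seed - q @ (q.T @ seed)
    rs_t = targets - (targets @ q) @ q.T
    zs = _standardize_rows(rs_seed[None, :])[0]
    zt = _standardize_rows(rs_t)
    return np.clip(zt @ zs / n, -1.0, 1.0)


def fc_map(
    dataset: BoldDataset,
    seed: VoxelSet,
    nuisance: NuisanceSet | None,
    labels: LabelTimeline,
    conditions,
    granularity: str = "voxel",
    radius_vox: float = 3.0,
    index: SearchlightIndex | None = None,
    subject: str | None = None,
) -> ConnectivityMap:
    """Seed-based functional-connectivity map over the IC-analyzed TRs.

    The seed's mean activation timeseries at the condition TRs is related
    to each target — every masked voxel's timeseries, or every
    searchlight's mean timeseries (``granularity="searchlight"``) — as the
    partial correlation given the nuisance covariates.
    """
    if granularity not in ("voxel", "searchlight"):
        raise ValueError("granularity must be 'voxel' or 'searchlight'")
    trs = select_condition_trs(labels, conditions)
    x = dataset.masked_timeseries()[:, trs]  # (n_vox, N)
    seed_idx = np.flatnonzero(seed.indicator(dataset.spatial_shape)[dataset.mask])
    if len(seed_idx) == 0:
        raise ValueError("seed contains no masked voxels")
    seed_series = x[seed_idx].mean(axis=0)

    if granularity == "searchlight":
        from .searchlight import searchlight_index

        if index is None:
            index = searchlight_index(dataset.mask, radius_vox)
        targets = np.asarray(index.matrix @ x) / index.n_members[:, None]
    else:
        targets = x
    cov = nuisance.regressors[trs] if nuisance is not None else None
    r = partial_correlation(seed_series, targets, cov)
    values = np.zeros(dataset.spatial_shape)
    if granularity == "searchlight":
        values = index.map_to_volume(r)
    else:
        values[dataset.mask] = r
    return ConnectivityMap(
        values=values,
        mask=dataset.mask,
        method="FC",
        seed=_seed_meta(seed),
        subject=subject,
    )


# ---------------------------------------------------------------------------
# map post-processing
# ---------------------------------------------------------------------------

def fisher_map(cmap: ConnectivityMap) -> ConnectivityMap:
    """Fisher-transform a correlation map into z-scores (elementwise artanh)."""
    if cmap.fisher_transformed:
        raise ValueError("map is already Fisher-transformed")
    values = cmap.values.copy()
    values[cmap.mask] = fisher_z(values[cmap.mask])
    return replace(cmap, values=values, fisher_transformed=True)


def smooth_map(
    cmap: ConnectivityMap,
    fwhm_mm: float,
    voxel_size_mm: np.ndarray,
) -> ConnectivityMap:
    """Mask-aware Gaussian smoothing.

    Per-axis sigma is ``(fwhm / voxel_size) / (2 sqrt(2 ln 2))`` in voxel
    units.  Values outside the mask are neither read nor written; the
    kernel is renormalized over its in-mask support, so a constant map is
    unchanged and edges are not attenuated.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return replace(cmap, values=cmap.values.copy(), smoothed_fwhm_mm=0.0)
    sigma = (fwhm_mm / np.asarray(voxel_size_mm, dtype=np.float64)) / FWHM_TO_SIGMA
    m = cmap.mask.astype(np.float64)
    num = ndi.gaussian_filter(cmap.values * m, sigma=sigma, mode="constant")
    den = ndi.gaussian_filter(m, sigma=sigma, mode="constant")
    out = np.zeros_like(cmap.values)
    inside = cmap.mask
    out[inside] = num[inside] / den[inside]
    return replace(cmap, values=out, smoothed_fwhm_mm=float(fwhm_mm))


def characterize_searchlights(
    dataset: BoldDataset,
    labels: LabelTimeline,
    conditions,
    radius_vox: float,
    maps: list[ConnectivityMap],
    seed: VoxelSet | None = None,
    sl_disc: SearchlightDiscriminability | None = None,
) -> pd.DataFrame:
    """Per-searchlight table of mean activation, decoding accuracy and
    connectivity strengths.

    Columns: center i/j/k, member count, mean activation over condition
    TRs, leave-one-run-out accuracy, one column per map (by method name),
    and a flag for searchlights overlapping the seed (flagged here, removed
    at reporting time).
    """
    if sl_disc is None:
        sl_disc = searchlight_discriminability(dataset, labels, conditions, radius_vox)
    index = sl_disc.index
    trs = select_condition_trs(labels, conditions)
    x = dataset.masked_timeseries()[:, trs]
    mean_act = np.asarray(index.matrix @ x.mean(axis=1)).ravel() / index.n_members
    table = pd.DataFrame(
        {
            "i": index.centers[:, 0],
            "j": index.centers[:, 1],
            "k": index.centers[:, 2],
            "n_members": index.n_members,
            "mean_activation": mean_act,
            "accuracy": sl_disc.accuracy(),
        }
    )
    for cmap in maps:
        if cmap.values.shape != index.mask.shape:
            raise ValueError("maps must share the dataset geometry")
        table[cmap.method] = cmap.values[tuple(index.centers.T)]
    table["overlaps_seed"] = index.overlaps(seed) if seed is not None else False
    return table
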