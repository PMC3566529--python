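"""Group-level inference with block-permutation cluster correction.

Per-subject Fisher-transformed, smoothed connectivity maps enter a
voxelwise one-sample t-test against zero (one-sided, positive).  Multiple
comparisons are corrected non-parametrically: each subject's seed series is
shuffled by swapping whole stimulus blocks (preserving within-block
autocorrelation), the subject maps are recomputed through the identical
Fisher/smoothing pipeline, group maps are assembled by sampling one
permuted map per subject, and the maximum suprathreshold cluster size of
each permuted group map forms the null distribution.  The alpha-quantile
order statistic of that null is the minimum cluster size; real clusters
strictly larger are significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy import stats

from .connectivity import ConnectivityMap

_STRUCTURES = {
    6: ndi.generate_binary_structure(3, 1),
    18: ndi.generate_binary_structure(3, 2),
    26: ndi.generate_binary_structure(3, 3),
}


@dataclass
class Cluster:
    size_voxels: int
    peak_t: float
    peak_voxel: tuple[int, int, int]
    center_voxel: tuple[int, int, int]
    members: np.ndarray


@dataclass
class NullDistribution:
    """Max-cluster sizes from permuted group maps."""

    max_cluster_sizes: np.ndarray
    n_group_maps: int
    n_subject_perms: int
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.max_cluster_sizes = np.asarray(self.max_cluster_sizes, dtype=np.int64)
        if len(self.max_cluster_sizes) != self.n_group_maps:
            raise ValueError("one max cluster size per group map required")
        if np.any(self.max_cluster_sizes < 0):
            raise ValueError("cluster sizes must be >= 0")


@dataclass
class GroupResult:
    """Thresholded group map with its corrected cluster table."""

    t_map: np.ndarray
    p_map: np.ndarray
    threshold_p: float
    min_cluster_size: int
    clusters: list[Cluster]
    n_subjects: int
    mask: np.ndarray | None = None
    significant_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        sig = np.zeros(self.t_map.shape, dtype=bool)
        for c in self.clusters:
            if c.size_voxels < self.min_cluster_size:
                raise ValueError("reported cluster below the minimum size")
            sig[tuple(c.members.T)] = True
        self.significant_mask = sig

    def cluster_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "size_voxels": c.size_voxels,
                    "peak_t": c.peak_t,
                    "peak_i": c.peak_voxel[0],
                    "peak_j": c.peak_voxel[1],
                    "peak_k": c.peak_voxel[2],
                    "center_i": c.center_voxel[0],
                    "center_j": c.center_voxel[1],
                    "center_k": c.center_voxel[2],
                }
                for c in self.clusters
            ],
            columns=[
                "size_voxels", "peak_t",
                "peak_i", "peak_j", "peak_k",
                "center_i", "center_j", "center_k",
            ],
        )


# ---------------------------------------------------------------------------
# voxelwise statistics
# ---------------------------------------------------------------------------

def group_ttest(maps: list, mask: np.ndarray | None = None):
    """Voxelwise one-sample t against zero with one-sided p (t > 0).

    ``maps`` are per-subject :class:`ConnectivityMap` objects or bare 3D
    arrays sharing geometry.  Voxels with zero across-subject variance get
    t = 0 and p = 1 (flagged degenerate by that convention).
    """
    arrays = [m.values if isinstance(m, ConnectivityMap) else np.asarray(m) for m in maps]
    if len(arrays) < 2:
        raise ValueError("group t-test needs at least 2 subjects")
    stack = np.stack(arrays)
    if mask is None:
        mask = (
            maps[0].mask
            if isinstance(maps[0], ConnectivityMap)
            else np.ones(stack.shape[1:], dtype=bool)
        )
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    t = np.zeros(mean.shape)
    p = np.ones(mean.shape)
    ok = mask & (sd > 1e-12)
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = stats.t.sf(t[ok], df=n - 1)
    return t, p


def label_clusters(binary_map: np.ndarray, connectivity: int = 6):
    """Connected components of a binary 3D map.

    Returns ``(labels, sizes)`` where labels is the component-id volume
    (0 = background) and sizes[i] is the voxel count of component i+1.
    ``connectivity`` selects face (6), edge (18) or corner (26) adjacency.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    labels, n = ndi.label(np.asarray(binary_map, dtype=bool), _STRUCTURES[connectivity])
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return labels, sizes


def max_cluster_size(binary_map: np.ndarray, connectivity: int = 6) -> int:
    _, sizes = label_clusters(binary_map, connectivity)
    return int(sizes.max()) if len(sizes) else 0


# ---------------------------------------------------------------------------
# block permutation
# ---------------------------------------------------------------------------

def permute_seed_series(
    values: np.ndarray,
    block_of_entry: np.ndarray,
    rng: np.random.Generator,
    run_of_entry: np.ndarray | None = None,
) -> np.ndarray:
    """Shuffle a seed series by randomly swapping whole blocks.

    Block-level positions are permuted uniformly; within-block order is
    preserved, so the multiset of values never changes.  Blocks are only
    exchanged with blocks of equal length (and, if ``run_of_entry`` is
    given, within the same run), which keeps the series structure intact
    when block lengths differ.
    """
    values = np.asarray(values)
    block_of_entry = np.asarray(block_of_entry)
    if values.shape != block_of_entry.shape:
        raise ValueError("values and block track must align")
    if np.any(block_of_entry < 0):
        raise ValueError("every entry must belong to a block")

    # contiguous index ranges per block, in temporal order
    uniq, first = np.unique(block_of_entry, return_index=True)
    order = np.argsort(first)
    slots = []
    for b in uniq[order]:
        idx = np.flatnonzero(block_of_entry == b)
        slots.append(idx)

    def group_key(idx):
        key = (len(idx),)
        if run_of_entry is not None:
            key = key + (int(np.asarray(run_of_entry)[idx[0]]),)
        return key

    out = np.empty_like(values)
    groups: dict = {}
    for si, idx in enumerate(slots):
        groups.setdefault(group_key(idx), []).append(si)
    for slot_ids in groups.values():
        perm = rng.permutation(len(slot_ids))
        for dst_pos, src_pos in zip(slot_ids, (slot_ids[j] for j in perm)):
            out[slots[dst_pos]] = values[slots[src_pos]]
    return out


# ---------------------------------------------------------------------------
# null distribution and correction
# ---------------------------------------------------------------------------

def build_null(
    subjects: list,
    pipeline,
    mask: np.ndarray,
    n_subject_perms: int = 100,
    n_group_maps: int = 1000,
    threshold_p: float = 0.001,
    connectivity: int = 6,
    rng: np.random.Generator | int | None = None,
) -> NullDistribution:
    """Null distribution of maximum cluster sizes under block permutation.

    ``pipeline(subject, rng)`` must return one permuted, fully processed
    (Fisher-transformed + smoothed) 3D map for that subject — the same
    processing the real maps receive.  Each of the ``n_group_maps`` group
    maps samples one permuted map per subject uniformly with replacement,
    runs the group t-test, thresholds at ``threshold_p`` (positive t) and
    records the largest surviving cluster (0 if none).
    """
    if n_subject_perms < 1:
        raise ValueError("n_subject_perms must be >= 1")
    if n_group_maps < 1:
        raise ValueError("n_group_maps must be >= 1")
    seed = int(rng) if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)

    perm_maps = [
        np.stack([pipeline(subj, rng) for _ in range(n_subject_perms)])
        for subj in subjects
    ]
    sizes = np.empty(n_group_maps, dtype=np.int64)
    for g in range(n_group_maps):
        draw = [pm[rng.integers(n_subject_perms)] for pm in perm_maps]
        t, p = group_ttest(draw, mask=mask)
        supra = mask & (p < threshold_p) & (t > 0)
        sizes[g] = max_cluster_size(supra, connectivity)
    return NullDistribution(
        max_cluster_sizes=sizes,
        n_group_maps=n_group_maps,
        n_subject_perms=n_subject_perms,
        rng_seed=seed,
    )


def corrected_min_cluster(null: NullDistribution, alpha: float = 0.05) -> int:
    """The k-th largest null max-cluster size, k = round(alpha * n).

    With 1000 permuted group maps and alpha = 0.05 this is the 50th
    largest size; real clusters strictly larger are significant at
    p < alpha, corrected.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    n = null.n_group_maps
    k = int(round(alpha * n))
    if k < 1:
        raise ValueError(f"alpha {alpha} too small for {n} group maps")
    return int(np.sort(null.max_cluster_sizes)[::-1][k - 1])


def apply_correction(
    t_map: np.ndarray,
    p_map: np.ndarray,
    mask: np.ndarray,
    threshold_p: float,
    min_cluster_size: int,
    n_subjects: int,
    connectivity: int = 6,
) -> GroupResult:
    """Keep clusters that survive the voxel threshold and are strictly
    larger than the permutation-derived minimum size."""
    supra = np.asarray(mask, dtype=bool) & (p_map < threshold_p) & (t_map > 0)
    labels, sizes = label_clusters(supra, connectivity)
    clusters: list[Cluster] = []
    for lab, size in enumerate(sizes, start=1):
        if size <= min_cluster_size:
            continue
        members = np.argwhere(labels == lab)
        ts = t_map[tuple(members.T)]
        peak = members[np.argmax(ts)]
        center = np.round(members.mean(axis=0)).astype(int)
        clusters.append(
            Cluster(
                size_voxels=int(size),
                peak_t=float(ts.max()),
                peak_voxel=tuple(int(v) for v in peak),
                center_voxel=tuple(int(v) for v in center),
                members=members,
            )
        )
    clusters.sort(key=lambda c: -c.size_voxels)
    return GroupResult(
        t_map=t_map,
        p_map=p_map,
        threshold_p=threshold_p,
        min_cluster_size=min_cluster_size,
        clusters=clusters,
        n_subjects=n_subjects,
        mask=np.asarray(mask, dtype=bool),
    )
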