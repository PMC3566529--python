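"""Loading and preprocessing of 4D BOLD data, labels and nuisance tables.

The preprocessing contract mirrors a standard block-design MVPA pipeline:
per-run polynomial detrending, nuisance residualization (six motion
parameters plus mean white-matter signal), per-run z-scoring, and a
condition-label shift that compensates for the hemodynamic delay.  The
canonical order is detrend -> residualize -> z-score, applied to the data,
followed by the label shift; :func:`preprocess` applies it in one call.

All TR indices are 0-based.  Rest time-points carry the label ``REST`` and
block id ``NO_BLOCK``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Condition label marking un-modelled (rest) time-points.
REST = "REST"
#: Block id assigned to rest time-points.
NO_BLOCK = -1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BoldDataset:
    """A 4D voxel timeseries with run structure and voxel geometry.

    Parameters
    ----------
    data
        4D float array indexed ``(i, j, k, t)``.
    voxel_size_mm
        Physical voxel dimensions, one positive value per spatial axis.
    tr_s
        Repetition time in seconds (sampling interval of the timeseries).
    run_of_tr
        Integer run id for every time-point; ids must form contiguous
        non-decreasing segments along time.
    mask
        3D boolean brain mask with the same spatial shape as ``data``.
    affine
        Optional 4x4 voxel-to-world transform, carried through unchanged.
    """

    data: np.ndarray
    voxel_size_mm: np.ndarray
    tr_s: float
    run_of_tr: np.ndarray
    mask: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=np.float64)
        self.run_of_tr = np.asarray(self.run_of_tr, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D, got shape {self.data.shape}")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match data spatial "
                f"shape {self.data.shape[:3]}"
            )
        if self.run_of_tr.shape != (self.data.shape[3],):
            raise ValueError("run_of_tr must have one entry per TR")
        if self.voxel_size_mm.shape != (3,) or np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel_size_mm must be 3 positive values")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        # run ids must be contiguous segments (non-repeating once left)
        ids = self.run_of_tr
        change = np.flatnonzero(np.diff(ids) != 0)
        segment_ids = ids[np.concatenate(([0], change + 1))]
        if len(set(segment_ids.tolist())) != len(segment_ids):
            raise ValueError("run ids must form contiguous segments along t")
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError("masked voxels contain non-finite values")

    @property
    def n_trs(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def runs(self) -> np.ndarray:
        """Run ids in temporal order of first appearance."""
        _, idx = np.unique(self.run_of_tr, return_index=True)
        return self.run_of_tr[np.sort(idx)]

    def run_slices(self) -> dict[int, slice]:
        """Map run id -> contiguous time slice."""
        out: dict[int, slice] = {}
        for run in self.runs:
            trs = np.flatnonzero(self.run_of_tr == run)
            out[int(run)] = slice(int(trs[0]), int(trs[-1]) + 1)
        return out

    def masked_timeseries(self) -> np.ndarray:
        """Return the masked data as a ``(n_voxels, n_trs)`` array (view-copy)."""
        return self.data[self.mask]

    def with_masked_timeseries(self, x: np.ndarray) -> "BoldDataset":
        """Return a copy whose masked voxels carry ``x`` (shape (n_vox, T))."""
        data = self.data.copy()
        data[self.mask] = x
        return replace(self, data=data)


@dataclass
class LabelTimeline:
    """Per-TR condition, run and block assignment.

    A block is a maximal set of contiguous TRs within one run sharing a
    non-rest condition.  Blocks never span runs; rest TRs carry
    ``NO_BLOCK``.  Block ids are recomputed from conditions and runs, in
    temporal order, whenever a timeline is constructed.
    """

    condition_of_tr: np.ndarray
    run_of_tr: np.ndarray
    block_of_tr: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.condition_of_tr = np.asarray(self.condition_of_tr, dtype=object)
        self.run_of_tr = np.asarray(self.run_of_tr, dtype=np.int64)
        if self.condition_of_tr.shape != self.run_of_tr.shape:
            raise ValueError("condition and run tracks must be equal length")
        self.block_of_tr = _compute_blocks(self.condition_of_tr, self.run_of_tr)

    @property
    def n_trs(self) -> int:
        return len(self.condition_of_tr)

    @property
    def conditions(self) -> list:
        """Sorted non-rest condition vocabulary."""
        labels = {c for c in self.condition_of_tr.tolist() if c != REST}
        return sorted(labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LabelTimeline":
        """Build from a table with columns ``tr``, ``run``, ``condition``."""
        df = df.sort_values("tr")
        if not np.array_equal(df["tr"].to_numpy(), np.arange(len(df))):
            raise ValueError("label table must cover TRs 0..T-1 exactly once")
        cond = df["condition"].astype(str).to_numpy(dtype=object)
        return cls(cond, df["run"].to_numpy())

    @classmethod
    def from_tsv(cls, path) -> "LabelTimeline":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tr": np.arange(self.n_trs),
                "run": self.run_of_tr,
                "condition": self.condition_of_tr,
                "block": self.block_of_tr,
            }
        )


@dataclass
class NuisanceSet:
    """Per-TR nuisance covariates (e.g. six motion parameters + WM mean)."""

    regressors: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=np.float64))
        if self.regressors.shape[1] != len(self.names):
            raise ValueError("one name per regressor column required")

    @property
    def n_trs(self) -> int:
        return self.regressors.shape[0]

    @classmethod
    def from_tsv(cls, path) -> "NuisanceSet":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(dtype=np.float64), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.regressors, columns=self.names)


def _compute_blocks(condition_of_tr: np.ndarray, run_of_tr: np.ndarray) -> np.ndarray:
    """Assign sequential block ids to maximal same-condition runs of TRs."""
    n = len(condition_of_tr)
    block = np.full(n, NO_BLOCK, dtype=np.int64)
    next_id = 0
    t = 0
    while t < n:
        if condition_of_tr[t] == REST:
            t += 1
            continue
        start = t
        while (
            t + 1 < n
            and condition_of_tr[t + 1] == condition_of_tr[start]
            and run_of_tr[t + 1] == run_of_tr[start]
        ):
            t += 1
        block[start : t + 1] = next_id
        next_id += 1
        t += 1
    return block


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_bold(volume_path, mask_path, run_table, tr_s: float | None = None) -> BoldDataset:
    """Load a 4D NIfTI volume, brain mask and run assignment.

    ``run_table`` may be a path to a TSV with columns ``tr`` and ``run``, a
    DataFrame with those columns, or a per-TR array of run ids.  The TR is
    read from the NIfTI header unless ``tr_s`` is given; a header without a
    usable TR requires an explicit ``tr_s``.
    """
    img = nib.load(str(volume_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"expected 4D volume, got shape {data.shape}")
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume spatial shape "
            f"{data.shape[:3]}"
        )
    zooms = img.header.get_zooms()
    voxel_size = np.asarray(zooms[:3], dtype=np.float64)
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr_s is None:
        if header_tr <= 0:
            raise ValueError("volume header carries no TR; pass tr_s explicitly")
        tr_s = header_tr

    if isinstance(run_table, (str,)) or hasattr(run_table, "__fspath__"):
        run_table = pd.read_csv(run_table, sep="\t")
    if isinstance(run_table, pd.DataFrame):
        run_table = run_table.sort_values("tr")["run"].to_numpy()
    run_of_tr = np.asarray(run_table, dtype=np.int64)
    return BoldDataset(
        data=data,
        voxel_size_mm=voxel_size,
        tr_s=float(tr_s),
        run_of_tr=run_of_tr,
        mask=mask,
        affine=np.asarray(img.affine),
    )


def save_bold(dataset: BoldDataset, path) -> None:
    """Write a dataset back to NIfTI-1, preserving geometry metadata."""
    affine = dataset.affine if dataset.affine is not None else np.eye(4)
    img = nib.Nifti1Image(dataset.data.astype(np.float32), affine)
    img.header.set_zooms(tuple(dataset.voxel_size_mm) + (dataset.tr_s,))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def detrend_polynomial(dataset: BoldDataset, order: int) -> BoldDataset:
    """Remove, per voxel and per run, a least-squares polynomial trend.

    The fitted component includes the run mean (the order-0 term), so
    residuals are mean-zero within each run.
    """
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    x = dataset.masked_timeseries().copy()
    for run, sl in dataset.run_slices().items():
        n = sl.stop - sl.start
        if n <= order + 1:
            raise ValueError(
                f"run {run} has {n} TRs, too short for polynomial order {order}"
            )
        t = np.linspace(-1.0, 1.0, n)
        basis = np.vander(t, order + 1, increasing=True)
        q, _ = np.linalg.qr(basis)
        seg = x[:, sl]
        x[:, sl] = seg - (seg @ q) @ q.T
    return dataset.with_masked_timeseries(x)


def residualize_nuisance(dataset: BoldDataset, nuisance: NuisanceSet) -> BoldDataset:
    """Regress nuisance covariates out of every voxel timeseries, per run.

    Each run's design is ``[intercept, regressors]``; residuals are
    orthogonal to every retained column.  All-zero or linearly dependent
    columns are dropped with a logged warning.
    """
    if nuisance.n_trs != dataset.n_trs:
        raise ValueError("nuisance rows must align with TRs")
    x = dataset.masked_timeseries().copy()
    for run, sl in dataset.run_slices().items():
        reg = nuisance.regressors[sl]
        keep = ~np.all(reg == 0, axis=0)
        if not np.all(keep):
            dropped = [n for n, k in zip(nuisance.names, keep) if not k]
            logger.warning("run %s: dropping all-zero regressors %s", run, dropped)
            reg = reg[:, keep]
        design = np.column_stack([np.ones(sl.stop - sl.start), reg])
        # drop linearly dependent columns via pivoted QR
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            import scipy.linalg

            _, _, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
            keep_cols = np.sort(piv[:rank])
            logger.warning(
                "run %s: design rank-deficient, keeping %d of %d columns",
                run, rank, design.shape[1],
            )
            design = design[:, keep_cols]
        q, _ = np.linalg.qr(design)
        seg = x[:, sl]
        x[:, sl] = seg - (seg @ q) @ q.T
    return dataset.with_masked_timeseries(x)


def zscore_within_run(dataset: BoldDataset) -> BoldDataset:
    """Normalize each voxel's timeseries to zero mean, unit variance per run.

    The sample standard deviation (n-1 denominator) over all of the run's
    TRs (task and rest alike) is used.  Voxels with zero variance in a run
    are set to zero for that run and logged, never dropped, so spatial
    shapes stay aligned.
    """
    x = dataset.masked_timeseries().copy()
    for run, sl in dataset.run_slices().items():
        seg = x[:, sl]
        mu = seg.mean(axis=1, keepdims=True)
        sd = seg.std(axis=1, ddof=1, keepdims=True)
        flat = sd[:, 0] < 1e-12
        if np.any(flat):
            logger.warning(
                "run %s: %d zero-variance voxels zeroed", run, int(flat.sum())
            )
        sd[flat] = 1.0
        seg = (seg - mu) / sd
        seg[flat] = 0.0
        x[:, sl] = seg
    return dataset.with_masked_timeseries(x)


def shift_labels(labels: LabelTimeline, shift_trs: int) -> LabelTimeline:
    """Shift condition labels later in time by ``shift_trs``, within runs.

    Compensates for the hemodynamic delay: the label at TR ``t`` moves to
    ``t + shift_trs``.  Labels shifted past a run's end are dropped (never
    wrapped), the vacated initial TRs become rest, and block ids are
    recomputed.
    """
    if shift_trs < 0:
        raise ValueError("shift_trs must be >= 0")
    cond = np.full(labels.n_trs, REST, dtype=object)
    runs = labels.run_of_tr
    for run in np.unique(runs):
        trs = np.flatnonzero(runs == run)
        n = len(trs)
        if shift_trs >= n:
            raise ValueError(f"shift {shift_trs} >= length of run {run} ({n})")
        if shift_trs == 0:
            cond[trs] = labels.condition_of_tr[trs]
        else:
            cond[trs[shift_trs:]] = labels.condition_of_tr[trs[:-shift_trs]]
    return LabelTimeline(cond, runs.copy())


def select_condition_trs(labels: LabelTimeline, conditions) -> np.ndarray:
    """Temporally ordered TR indices whose label is in ``conditions``.

    The position in the returned list defines the trial index n = 1..N of
    the discriminability timeseries.
    """
    conditions = list(conditions)
    if not conditions:
        raise ValueError("conditions must be nonempty")
    vocab = set(labels.conditions)
    unknown = [c for c in conditions if c not in vocab]
    if unknown:
        raise ValueError(f"unknown condition ids: {unknown} (have {sorted(vocab)})")
    wanted = set(conditions)
    idx = np.flatnonzero([c in wanted for c in labels.condition_of_tr])
    if len(idx) == 0:
        raise ValueError("no TRs carry the requested conditions")
    return idx


def preprocess(
    dataset: BoldDataset,
    labels: LabelTimeline,
    nuisance: NuisanceSet | None = None,
    detrend_order: int = 2,
    shift_trs: int = 2,
) -> tuple[BoldDataset, LabelTimeline]:
    """Apply the full preprocessing contract in canonical order.

    Detrend (default 2nd-order polynomial), residualize nuisance covariates
    if given, z-score within run, and shift labels (default 2 TRs).
    """
    out = detrend_polynomial(dataset, detrend_order)
    if nuisance is not None:
        out = residualize_nuisance(out, nuisance)
    out = zscore_within_run(out)
    return out, shift_labels(labels, shift_trs)
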