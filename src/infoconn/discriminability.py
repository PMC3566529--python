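"""Per-time-point multi-voxel pattern discriminability.

For every labeled TR the activity pattern of a voxel set is correlated
(Pearson) with the leave-one-run-out mean pattern (prototype) of each
condition.  The discriminability value is

    artanh(r_correct) - artanh(max over incorrect r)

i.e. the Fisher-z similarity to the correct condition's prototype minus the
Fisher-z similarity to the most confusable incorrect prototype.  A positive
value means the standard correlation-based classifier would predict the TR's
condition correctly; the timeseries of values across the session is the
signal that informational connectivity correlates between regions.

Two computation paths are provided: :func:`discriminability_timeseries` is
the straightforward per-voxel-set reference, and
:func:`searchlight_discriminability` evaluates every searchlight in a mask
at once from sparse running sums.  The two agree to floating-point
precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_preproc import BoldDataset, LabelTimeline, select_condition_trs
from .searchlight import SearchlightIndex, VoxelSet, searchlight_index

logger = logging.getLogger(__name__)

#: Correlations are clipped to +/-(1 - ARTANH_CLIP) before the Fisher
#: transform so a test pattern identical to a prototype stays finite.
ARTANH_CLIP = 1e-7

_DEGENERATE = object()  # internal marker for zero-variance patterns


@dataclass
class PrototypeSet:
    """Leave-one-run-out condition prototypes for one voxel set."""

    held_out_run: int
    prototype_of_condition: dict
    m: int

    def __post_init__(self) -> None:
        for cond, proto in self.prototype_of_condition.items():
            proto = np.asarray(proto, dtype=np.float64)
            if proto.shape != (self.m,):
                raise ValueError(f"prototype for {cond!r} has wrong length")
            self.prototype_of_condition[cond] = proto

    @property
    def conditions(self) -> list:
        return sorted(self.prototype_of_condition)


@dataclass
class DiscriminabilityTimeseries:
    """Discriminability values for one voxel set, in trial order n = 1..N."""

    values: np.ndarray
    tr_index: np.ndarray
    condition: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.values)
        if not (len(self.tr_index) == len(self.condition) == len(self.predicted) == n):
            raise ValueError("all tracks must share the trial length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("discriminability values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def to_dataframe(self, run_of_tr: np.ndarray | None = None) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "tr": self.tr_index,
                "condition": self.condition,
                "value": self.values,
                "predicted": self.predicted,
            }
        )
        if run_of_tr is not None:
            out.insert(1, "run", np.asarray(run_of_tr)[self.tr_index])
        return out


# ---------------------------------------------------------------------------
# scalar building blocks
# ---------------------------------------------------------------------------

def pattern_correlation(x: np.ndarray, prototype: np.ndarray) -> float:
    """Pearson correlation between a test pattern and a prototype.

    Defined through the standard Pearson formula, which coincides with the
    normalized-vector dot product over m-1.  A constant (zero-variance)
    input yields 0 by convention.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(prototype, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("patterns must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("patterns need at least 3 voxels")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom < 1e-300:
        return 0.0
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """artanh with clipping to keep |r| strictly below 1."""
    return np.arctanh(np.clip(r, -1.0 + ARTANH_CLIP, 1.0 - ARTANH_CLIP))


def fit_prototypes(
    patterns_by_tr: np.ndarray,
    labels: LabelTimeline,
    held_out_run: int,
    conditions,
) -> PrototypeSet:
    """Mean training pattern per condition, excluding the held-out run.

    ``patterns_by_tr`` is a (T, m) array of the voxel set's values at every
    TR of the session.
    """
    patterns_by_tr = np.asarray(patterns_by_tr, dtype=np.float64)
    if len(np.unique(labels.run_of_tr)) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    protos: dict = {}
    train = labels.run_of_tr != held_out_run
    for cond in conditions:
        rows = train & (labels.condition_of_tr == cond)
        if not rows.any():
            raise ValueError(
                f"condition {cond!r} absent from training runs "
                f"(held out run {held_out_run})"
            )
        protos[cond] = patterns_by_tr[rows].mean(axis=0)
    return PrototypeSet(
        held_out_run=int(held_out_run),
        prototype_of_condition=protos,
        m=patterns_by_tr.shape[1],
    )


def _classify(x: np.ndarray, protoset: PrototypeSet):
    """Correlations with each prototype plus the argmax prediction.

    Ties are broken toward the condition earliest in sorted order; a
    zero-variance test pattern is flagged degenerate.
    """
    conds = protoset.conditions
    if np.ptp(x) == 0:
        return {c: 0.0 for c in conds}, _DEGENERATE
    rs = {c: pattern_correlation(x, protoset.prototype_of_condition[c]) for c in conds}
    best = max(conds, key=lambda c: (rs[c], -conds.index(c)))
    # max() keeps the first of equals given the key; make tie-break explicit
    top = max(rs.values())
    winners = [c for c in conds if rs[c] == top]
    return rs, winners[0]


def discriminability_at_tr(
    x: np.ndarray, protoset: PrototypeSet, correct_condition
) -> float:
    """Fisher-z margin of the correct prototype over the best incorrect one."""
    conds = protoset.conditions
    if len(conds) < 2:
        raise ValueError("at least 2 conditions required")
    if correct_condition not in protoset.prototype_of_condition:
        raise ValueError(f"no prototype for condition {correct_condition!r}")
    rs, pred = _classify(np.asarray(x, dtype=np.float64), protoset)
    if pred is _DEGENERATE:
        return 0.0
    r_c = rs[correct_condition]
    r_i = max(r for c, r in rs.items() if c != correct_condition)
    return float(fisher_z(r_c) - fisher_z(r_i))


# ---------------------------------------------------------------------------
# timeseries (reference path)
# ---------------------------------------------------------------------------

def discriminability_timeseries(
    dataset: BoldDataset,
    voxel_set: VoxelSet,
    labels: LabelTimeline,
    conditions,
) -> DiscriminabilityTimeseries:
    """Full leave-one-run-out discriminability series for one voxel set.

    For each labeled TR the prototypes trained on all other runs are used;
    trial order follows temporal order of the selected TRs.
    """
    conditions = sorted(conditions)
    trs = select_condition_trs(labels, conditions)
    x_all = dataset.data[tuple(voxel_set.members.T)].T  # (T, m)
    values = np.empty(len(trs))
    predicted = np.empty(len(trs), dtype=object)
    cond_of = labels.condition_of_tr
    for run in np.unique(labels.run_of_tr[trs]):
        protoset = fit_prototypes(x_all, labels, run, conditions)
        for pos in np.flatnonzero(labels.run_of_tr[trs] == run):
            t = trs[pos]
            rs, pred = _classify(x_all[t], protoset)
            if pred is _DEGENERATE:
                logger.warning("TR %d: zero-variance pattern, counted incorrect", t)
                values[pos] = 0.0
                predicted[pos] = None
                continue
            correct = cond_of[t]
            r_i = max(r for c, r in rs.items() if c != correct)
            values[pos] = fisher_z(rs[correct]) - fisher_z(r_i)
            predicted[pos] = pred
    return DiscriminabilityTimeseries(
        values=values,
        tr_index=trs,
        condition=cond_of[trs].copy(),
        predicted=predicted,
    )


def classification_accuracy(series: DiscriminabilityTimeseries) -> float:
    """Proportion of TRs whose predicted condition matches the true one."""
    if len(series) == 0:
        raise ValueError("empty discriminability series")
    correct = [p == c for p, c in zip(series.predicted, series.condition)]
    return float(np.mean(correct))


# ---------------------------------------------------------------------------
# whole-brain searchlight engine
# ---------------------------------------------------------------------------

@dataclass
class SearchlightDiscriminability:
    """Discriminability of every searchlight in a mask, trial-aligned.

    ``values`` has shape (n_centers, N): row i is the discriminability
    timeseries of the searchlight centered at ``index.centers[i]``.
    """

    index: SearchlightIndex
    values: np.ndarray
    tr_index: np.ndarray
    condition: np.ndarray
    correct: np.ndarray  # bool (n_centers, N): argmax prediction correct

    def accuracy(self) -> np.ndarray:
        """Per-center leave-one-run-out classification accuracy."""
        return self.correct.mean(axis=1)

    def series_at(self, center_row: int) -> DiscriminabilityTimeseries:
        pred = np.where(self.correct[center_row], self.condition, None)
        return DiscriminabilityTimeseries(
            values=self.values[center_row],
            tr_index=self.tr_index,
            condition=self.condition,
            predicted=pred,
        )


def _sums_to_correlation(m, sx, sxx, sy, syy, sxy):
    """Pearson r from running sums; zero-variance pairs map to r = 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        vx = np.maximum(m * sxx - sx**2, 0.0)
        vy = np.maximum(m * syy - sy**2, 0.0)
        num = m * sxy - sx * sy
        denom = np.sqrt(vx * vy)
        r = np.where(denom > 1e-12, num / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def searchlight_discriminability(
    dataset: BoldDataset,
    labels: LabelTimeline,
    conditions,
    radius_vox: float = 3.0,
    index: SearchlightIndex | None = None,
) -> SearchlightDiscriminability:
    """Leave-one-run-out discriminability series for every searchlight.

    Equivalent to running :func:`discriminability_timeseries` on each
    truncated sphere of :func:`iter_searchlights`, but computed from sparse
    per-sphere running sums so the whole brain is a handful of sparse-dense
    products per cross-validation fold.
    """
    conditions = sorted(conditions)
    if len(conditions) < 2:
        raise ValueError("at least 2 conditions required")
    if index is None:
        index = searchlight_index(dataset.mask, radius_vox)
    S = index.matrix
    m = index.n_members.astype(np.float64)

    trs = select_condition_trs(labels, conditions)
    n_trials = len(trs)
    x = dataset.masked_timeseries()  # (n_vox, T)
    cond_of = labels.condition_of_tr
    run_of = labels.run_of_tr

    values = np.empty((index.n_centers, n_trials))
    r_by_cond = np.empty((len(conditions), index.n_centers))
    correct = np.zeros((index.n_centers, n_trials), dtype=bool)

    for run in np.unique(run_of[trs]):
        train = (run_of != run)
        # prototypes over all masked voxels
        protos = []
        for cond in conditions:
            rows = train & (cond_of == cond)
            if not rows.any():
                raise ValueError(
                    f"condition {cond!r} absent from training runs "
                    f"(held out run {run})"
                )
            protos.append(x[:, rows].mean(axis=1))
        proto_sums = [(S @ p, S @ (p * p)) for p in protos]

        test_pos = np.flatnonzero(run_of[trs] == run)
        xt = x[:, trs[test_pos]]  # (n_vox, n_test)
        sx = S @ xt  # (n_centers, n_test)
        sxx = S @ (xt * xt)
        sxy_by_cond = [S @ (xt * p[:, None]) for p in protos]
        for j, pos in enumerate(test_pos):
            r_stack = r_by_cond
            for ci, (sy, syy) in enumerate(proto_sums):
                r_stack[ci] = _sums_to_correlation(
                    m, sx[:, j], sxx[:, j], sy, syy, sxy_by_cond[ci][:, j]
                )
            correct_ci = conditions.index(cond_of[trs[pos]])
            r_c = r_stack[correct_ci]
            r_i = np.max(np.delete(r_stack, correct_ci, axis=0), axis=0)
            values[:, pos] = fisher_z(r_c) - fisher_z(r_i)
            # argmax with first-of-sorted tie-break = np.argmax over sorted conds
            correct[:, pos] = np.argmax(r_stack, axis=0) == correct_ci
            # degenerate searchlights (all-zero variance): tie -> incorrect
            degen = np.all(r_stack == 0.0, axis=0)
            if degen.any():
                correct[degen, pos] = False
                values[degen, pos] = 0.0

    return SearchlightDiscriminability(
        index=index,
        values=values,
        tr_index=trs,
        condition=cond_of[trs].copy(),
        correct=correct,
    )
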