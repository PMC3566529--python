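"""Synthetic multi-run block-design fMRI with known connectivity structure.

The generator emulates the session layout of a classic object-viewing
block experiment: 12 runs, four conditions, one 9-TR block per condition
per run separated by rest, TR = 2.5 s.  Each simulated region carries a
fixed zero-mean spatial pattern per condition whose amplitude (pattern
signal-to-noise) fluctuates block by block, plus a univariate mean offset
that fluctuates block by block.  Regions that share an
``snr_coupling_group`` share the pattern-SNR fluctuation series — the
ground truth that informational connectivity should recover; regions that
share a ``univariate_coupling_group`` share the mean fluctuation series —
the ground truth for seed-based functional connectivity.  Everything else
is i.i.d. Gaussian noise.

Signal is injected ``hemodynamic_delay_trs`` after the stimulus labels, so
the analysis-side label shift re-aligns labels with signal, mirroring how
a hemodynamic delay is handled on real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io_preproc import REST, BoldDataset, LabelTimeline, NuisanceSet
from .searchlight import VoxelSet, build_sphere

DEFAULT_CONDITIONS = ("bottle", "chair", "scissors", "shoe")


@dataclass
class RegionSpec:
    """One simulated region and its latent coupling structure.

    ``base_snr`` scales the condition pattern (units of noise SD for the
    whole m-voxel pattern, which has unit norm); ``base_mean_amplitude``
    scales the shared additive mean offset.  Coupling group ids tie the
    block-wise fluctuation series of different regions together.
    """

    name: str
    voxels: VoxelSet
    condition_patterns: dict
    base_snr: float = 3.0
    base_mean_amplitude: float = 1.0
    snr_coupling_group: str | None = None
    univariate_coupling_group: str | None = None

    def __post_init__(self) -> None:
        pats = {c: np.asarray(p, dtype=np.float64) for c, p in self.condition_patterns.items()}
        for c, p in pats.items():
            if p.shape != (self.voxels.n_members,):
                raise ValueError(f"pattern for {c!r} must have one value per voxel")
        conds = sorted(pats)
        for a in range(len(conds)):
            for b in range(a + 1, len(conds)):
                pa, pb = pats[conds[a]], pats[conds[b]]
                na, nb = np.linalg.norm(pa), np.linalg.norm(pb)
                if na > 0 and nb > 0 and abs(pa @ pb) / (na * nb) >= 0.9:
                    raise ValueError(
                        f"patterns for {conds[a]!r} and {conds[b]!r} too similar"
                    )
        self.condition_patterns = pats


@dataclass
class SyntheticSpec:
    """Full description of a simulated multi-subject experiment."""

    volume_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: tuple[float, float, float] = (3.5, 3.75, 3.75)
    tr_s: float = 2.5
    n_runs: int = 12
    conditions: tuple = DEFAULT_CONDITIONS
    block_trs: int = 9
    rest_trs: int = 5
    regions: list = field(default_factory=list)
    noise_sd: float = 1.0
    rng_seed: int = 0
    n_subjects: int = 10
    snr_fluctuation_sd: float = 0.5
    univariate_fluctuation_sd: float = 0.5
    hemodynamic_delay_trs: int = 2
    #: Redraw each region's condition patterns per subject (emulating
    #: subject-unique fine-grained pattern geometry, as on real data).
    #: When False the RegionSpec patterns are shared by all subjects,
    #: which makes stimulus-locked pattern structure a group-level
    #: confound — exactly as fixed functional architecture would.
    patterns_per_subject: bool = True

    def __post_init__(self) -> None:
        if self.block_trs < 1:
            raise ValueError("block_trs must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        seen: set = set()
        for reg in self.regions:
            vox = {tuple(v) for v in reg.voxels.members}
            if vox & seen:
                raise ValueError(f"region {reg.name!r} overlaps another region")
            seen |= vox

    @property
    def run_trs(self) -> int:
        """TRs per run: leading rest plus one block+rest per condition."""
        return self.rest_trs + len(self.conditions) * (self.block_trs + self.rest_trs)

    @property
    def n_trs(self) -> int:
        return self.run_trs * self.n_runs


def make_patterns(
    n_voxels: int,
    conditions,
    rng: np.random.Generator,
    max_abs_corr: float = 0.0,
) -> dict:
    """Zero-mean, unit-norm spatial patterns with bounded pairwise correlation.

    With the default bound of 0 the patterns are mutually orthogonal
    (Gram-Schmidt in the zero-mean subspace); looser bounds accept raw
    demeaned Gaussian draws whose empirical correlations stay below the
    bound.
    """
    conditions = list(conditions)
    if n_voxels < len(conditions) + 2:
        raise ValueError("need at least n_conditions + 2 voxels")
    for _ in range(100):
        g = rng.standard_normal((n_voxels, len(conditions)))
        g -= g.mean(axis=0, keepdims=True)
        if max_abs_corr <= 0:
            q, _ = np.linalg.qr(g)
            vecs = q.T
        else:
            vecs = (g / np.linalg.norm(g, axis=0, keepdims=True)).T
            cc = np.corrcoef(vecs)
            np.fill_diagonal(cc, 0.0)
            if np.abs(cc).max() >= max_abs_corr:
                continue
        vecs = vecs - vecs.mean(axis=1, keepdims=True)
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        return {c: vecs[i] for i, c in enumerate(conditions)}
    raise ValueError(f"could not satisfy correlation bound {max_abs_corr}")


def _session_labels(spec: SyntheticSpec, rng: np.random.Generator) -> LabelTimeline:
    """Block order is randomized within each run."""
    cond = np.full(spec.n_trs, REST, dtype=object)
    runs = np.repeat(np.arange(spec.n_runs), spec.run_trs)
    for run in range(spec.n_runs):
        t = run * spec.run_trs + spec.rest_trs
        for c in rng.permutation(np.asarray(spec.conditions, dtype=object)):
            cond[t : t + spec.block_trs] = c
            t += spec.block_trs + spec.rest_trs
    return LabelTimeline(cond, runs)


def _smooth_series(rng: np.random.Generator, n: int, scale: float = 1.0) -> np.ndarray:
    """Slowly varying nuisance-like series (cumulative noise, demeaned)."""
    s = np.cumsum(rng.normal(0.0, scale, n))
    return s - s.mean()


def generate_subject(
    spec: SyntheticSpec, subject_index: int
) -> tuple[BoldDataset, LabelTimeline, NuisanceSet, dict]:
    """Simulate one subject's session.

    Returns the raw (un-preprocessed) dataset, the stimulus-locked label
    timeline, a nuisance table of smooth random series (which contribute
    nothing to the data, so residualization is a statistical no-op), and a
    ground-truth manifest recording every latent fluctuation series.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.rng_seed), int(subject_index)])
    )
    labels = _session_labels(spec, rng)
    patterns = [
        make_patterns(reg.voxels.n_members, spec.conditions, rng)
        if spec.patterns_per_subject
        else reg.condition_patterns
        for reg in spec.regions
    ]
    data = rng.normal(0.0, spec.noise_sd, spec.volume_shape + (spec.n_trs,))

    # enumerate blocks in temporal order
    blocks = []
    for b in np.unique(labels.block_of_tr[labels.block_of_tr >= 0]):
        trs = np.flatnonzero(labels.block_of_tr == b)
        blocks.append(
            {
                "block": int(b),
                "run": int(labels.run_of_tr[trs[0]]),
                "condition": labels.condition_of_tr[trs[0]],
                "trs": trs,
            }
        )
    n_blocks = len(blocks)

    # latent block-wise fluctuation series, shared within coupling groups
    def draw_series(sd: float) -> np.ndarray:
        return np.exp(rng.normal(0.0, sd, n_blocks))  # log-normal, median 1

    snr_series: dict = {}
    uni_series: dict = {}
    for ri, reg in enumerate(spec.regions):
        skey = reg.snr_coupling_group or f"__solo_snr_{ri}"
        ukey = reg.univariate_coupling_group or f"__solo_uni_{ri}"
        if skey not in snr_series:
            snr_series[skey] = draw_series(spec.snr_fluctuation_sd)
        if ukey not in uni_series:
            uni_series[ukey] = draw_series(spec.univariate_fluctuation_sd)

    delay = spec.hemodynamic_delay_trs
    run_end = {
        int(r): int(np.flatnonzero(labels.run_of_tr == r)[-1])
        for r in np.unique(labels.run_of_tr)
    }
    for ri, reg in enumerate(spec.regions):
        vox = tuple(reg.voxels.members.T)
        skey = reg.snr_coupling_group or f"__solo_snr_{ri}"
        ukey = reg.univariate_coupling_group or f"__solo_uni_{ri}"
        for bi, blk in enumerate(blocks):
            trs = blk["trs"] + delay
            trs = trs[trs <= run_end[blk["run"]]]
            if len(trs) == 0:
                continue
            amp_mean = reg.base_mean_amplitude * uni_series[ukey][bi]
            amp_pat = reg.base_snr * snr_series[skey][bi]
            pattern = patterns[ri][blk["condition"]]
            add = amp_mean + amp_pat * pattern[:, None]
            data[vox[0], vox[1], vox[2], trs[0] : trs[-1] + 1] += add
    mask = np.ones(spec.volume_shape, dtype=bool)

    # Nuisance series are smooth random walks made orthogonal, per run, to
    # the signal-support boxcar: they emulate motion/WM series that are not
    # task-correlated, so residualizing them out cannot remove (or inject)
    # task-locked structure.  Task-correlated nuisance is a known separate
    # confound and is deliberately not simulated here.
    names = ["pitch", "roll", "yaw", "x", "y", "z", "wm_mean"]
    reg_mat = np.column_stack(
        [_smooth_series(rng, spec.n_trs, 0.05) for _ in names]
    )
    signal_support = np.zeros(spec.n_trs)
    for blk in blocks:
        trs = blk["trs"] + delay
        trs = trs[trs <= run_end[blk["run"]]]
        signal_support[trs] = 1.0
    for r in np.unique(labels.run_of_tr):
        sl = np.flatnonzero(labels.run_of_tr == r)
        design = np.column_stack([np.ones(len(sl)), signal_support[sl]])
        q, _ = np.linalg.qr(design)
        reg_mat[sl] -= q @ (q.T @ reg_mat[sl])
    nuisance = NuisanceSet(reg_mat, names)

    dataset = BoldDataset(
        data=data,
        voxel_size_mm=np.asarray(spec.voxel_size_mm),
        tr_s=spec.tr_s,
        run_of_tr=labels.run_of_tr.copy(),
        mask=mask,
        affine=np.diag(list(spec.voxel_size_mm) + [1.0]),
    )
    manifest = {
        "subject_index": int(subject_index),
        "rng_seed": int(spec.rng_seed),
        "hemodynamic_delay_trs": delay,
        "patterns_per_subject": spec.patterns_per_subject,
        "blocks": [
            {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in b.items()}
            for b in blocks
        ],
        "snr_series": {k: v.tolist() for k, v in snr_series.items()},
        "univariate_series": {k: v.tolist() for k, v in uni_series.items()},
        "regions": [
            {
                "name": r.name,
                "center": list(r.voxels.center),
                "n_voxels": r.voxels.n_members,
                "base_snr": r.base_snr,
                "base_mean_amplitude": r.base_mean_amplitude,
                "snr_coupling_group": r.snr_coupling_group,
                "univariate_coupling_group": r.univariate_coupling_group,
            }
            for r in spec.regions
        ],
    }
    return dataset, labels, nuisance, manifest


def default_block_design(
    rng_seed: int = 0,
    n_subjects: int = 10,
    volume_shape: tuple[int, int, int] = (20, 20, 20),
    base_snr: float = 3.0,
    base_mean_amplitude: float = 1.0,
    decoupled: bool = False,
) -> SyntheticSpec:
    """The canonical simulated experiment: 12 runs x 4 conditions x 9-TR
    blocks with four regions exercising every connectivity contrast.

    Regions (all 123-voxel radius-3 spheres):

    * ``seed`` — condition patterns and a univariate response; shares its
      pattern-SNR fluctuations with ``info_partner`` and its univariate
      fluctuations with ``uni_partner``.
    * ``info_partner`` — patterns coupled to the seed's SNR series but a
      flat univariate mean: high IC with the seed, near-zero FC.
    * ``uni_partner`` — no condition information (base_snr = 0) but a mean
      coupled to the seed's univariate series: high FC, near-zero IC.
    * ``independent`` — patterns and mean with private fluctuation series:
      neither IC nor FC.

    ``decoupled=True`` gives every region private fluctuation series (a
    global-null configuration for type-I error checks).
    """
    rng = np.random.default_rng(rng_seed)
    if min(volume_shape) < 12:
        raise ValueError("volume must be at least 12 voxels per axis")
    mask = np.ones(volume_shape, dtype=bool)
    # four disjoint radius-3 spheres on alternating corners of an inner cube
    lo = [max(3, int(round(n / 4))) for n in volume_shape]
    hi = [min(n - 4, int(round(3 * n / 4))) for n in volume_shape]
    centers = {
        "seed": (lo[0], lo[1], lo[2]),
        "info_partner": (lo[0], hi[1], hi[2]),
        "uni_partner": (hi[0], lo[1], hi[2]),
        "independent": (hi[0], hi[1], lo[2]),
    }
    couplings = {
        "seed": ("info", "uni"),
        "info_partner": ("info", None),
        "uni_partner": (None, "uni"),
        "independent": (None, None),
    }
    if decoupled:
        couplings = {name: (None, None) for name in couplings}
    amplitudes = {
        "seed": (base_snr, base_mean_amplitude),
        "info_partner": (base_snr, 0.0),
        "uni_partner": (0.0, base_mean_amplitude),
        "independent": (base_snr, base_mean_amplitude),
    }
    regions = []
    for name, center in centers.items():
        vox = build_sphere(center, 3.0, mask)
        pats = make_patterns(vox.n_members, DEFAULT_CONDITIONS, rng)
        snr_g, uni_g = couplings[name]
        snr_amp, mean_amp = amplitudes[name]
        regions.append(
            RegionSpec(
                name=name,
                voxels=vox,
                condition_patterns=pats,
                base_snr=snr_amp,
                base_mean_amplitude=mean_amp,
                snr_coupling_group=snr_g,
                univariate_coupling_group=uni_g,
            )
        )
    return SyntheticSpec(
        volume_shape=volume_shape,
        regions=regions,
        rng_seed=rng_seed,
        n_subjects=n_subjects,
    )


def save_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
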