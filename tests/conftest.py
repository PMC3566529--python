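"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest

from infoconn import (
    BoldDataset,
    LabelTimeline,
    RegionSpec,
    SyntheticSpec,
    build_sphere,
    generate_subject,
    make_patterns,
    preprocess,
)


def make_dataset(data, runs_of_tr=None, mask=None, voxel_size=(1.0, 1.0, 1.0), tr_s=1.0):
    """BoldDataset from a raw 4D array with sensible defaults."""
    data = np.asarray(data, dtype=float)
    if runs_of_tr is None:
        runs_of_tr = np.zeros(data.shape[3], dtype=int)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldDataset(
        data=data,
        voxel_size_mm=np.asarray(voxel_size),
        tr_s=tr_s,
        run_of_tr=np.asarray(runs_of_tr),
        mask=mask,
    )


@pytest.fixture(scope="session")
def tiny_spec():
    """Small two-region session: coupled pair in a 12^3 volume, 4 runs."""
    mask = np.ones((12, 12, 12), dtype=bool)
    rng = np.random.default_rng(99)
    conds = ("bottle", "chair", "scissors", "shoe")
    regions = []
    for name, center, group in [
        ("a", (3, 3, 3), "shared"),
        ("b", (8, 8, 8), "shared"),
    ]:
        vox = build_sphere(center, 2.0, mask)
        regions.append(
            RegionSpec(
                name=name,
                voxels=vox,
                condition_patterns=make_patterns(vox.n_members, conds, rng),
                base_snr=3.0,
                base_mean_amplitude=1.0,
                snr_coupling_group=group,
            )
        )
    return SyntheticSpec(
        volume_shape=(12, 12, 12),
        n_runs=4,
        conditions=conds,
        block_trs=4,
        rest_trs=3,
        regions=regions,
        rng_seed=99,
    )


@pytest.fixture(scope="session")
def tiny_subject(tiny_spec):
    """One generated subject: (raw dataset, labels, nuisance, manifest)."""
    return generate_subject(tiny_spec, 0)


@pytest.fixture(scope="session")
def tiny_preprocessed(tiny_subject, tiny_spec):
    """Preprocessed tiny subject: (dataset, shifted labels)."""
    ds, labels, nuisance, _ = tiny_subject
    return preprocess(
        ds, labels, None, detrend_order=0,
        shift_trs=tiny_spec.hemodynamic_delay_trs,
    )


@pytest.fixture
def simple_labels():
    """Two runs of 10 TRs each with one 4-TR block of each condition."""
    cond = np.array(["REST"] * 20, dtype=object)
    runs = np.repeat([0, 1], 10)
    cond[2:6] = "x"
    cond[6:10] = "y"
    cond[12:16] = "y"
    cond[16:20] = "x"
    return LabelTimeline(cond, runs)
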