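"""Shared fixtures: tiny synthetic runs and campaigns built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from lcqc import chem
from lcqc.io_formats import CentroidRun, TargetFeature
from lcqc.synthetic import CampaignSpec, SequenceSpec, SyntheticFeature


def make_run(rts, mzs, intensities, **kw) -> CentroidRun:
    """Build a CentroidRun from plain lists, sorting each scan by m/z."""
    mz_arrays, iy_arrays = [], []
    for mz, iy in zip(mzs, intensities):
        mz = np.asarray(mz, dtype=np.float64)
        iy = np.asarray(iy, dtype=np.float64)
        order = np.argsort(mz, kind="stable")
        mz_arrays.append(mz[order])
        iy_arrays.append(iy[order])
    return CentroidRun(rts=np.asarray(rts, dtype=np.float64), mzs=mz_arrays, intensities=iy_arrays, **kw)


def random_run(rng: np.random.Generator, n_scans: int = 30, max_peaks: int = 40) -> CentroidRun:
    """A random centroid run for oracle-equivalence checks."""
    rts = np.cumsum(rng.uniform(0.5, 2.0, size=n_scans))
    mzs, iys = [], []
    for _ in range(n_scans):
        k = rng.integers(0, max_peaks)
        mzs.append(np.sort(rng.uniform(100.0, 500.0, size=k)))
        iys.append(rng.exponential(1e4, size=k))
    return CentroidRun(rts=rts, mzs=mzs, intensities=iys)


def small_features():
    return (
        SyntheticFeature("Jasmonic acid", "C12H18O3", rt_s=150.0, sigma_s=5.0, apex_intensity=6e4),
        SyntheticFeature("Caffeic acid", "C9H8O4", rt_s=80.0, sigma_s=5.0, apex_intensity=9e4),
    )


def targets_for(features) -> list:
    return [
        TargetFeature(
            name=f.name,
            ion=chem.get_ion(f.ion_label),
            expected_rt_s=f.rt_s,
            formula=chem.parse_formula(f.formula),
        )
        for f in features
    ]


@pytest.fixture(scope="session")
def clean_campaign_dir(tmp_path_factory):
    """A defect-free two-sequence campaign on disk (shared across tests)."""
    from lcqc.synthetic import write_campaign

    spec = CampaignSpec(
        features=small_features(),
        sequences=(
            SequenceSpec("sequence1", categories=(("QCstd", 4), ("blank", 1))),
            SequenceSpec("sequence2", categories=(("QCstd", 4), ("blank", 1))),
        ),
        rt_max_s=220.0,
        seed=101,
    )
    out = tmp_path_factory.mktemp("clean_campaign")
    truth = write_campaign(spec, out, force=True)
    return spec, out, truth


@pytest.fixture(scope="session")
def defect_campaign_dir(tmp_path_factory):
    """Two sequences of 12 QC standards with a 2× sensitivity step and a
    −5 → +5 ppm linear mass drift in the second sequence."""
    from lcqc.synthetic import qc_standard_campaign, write_campaign

    spec = qc_standard_campaign(seed=42, features=small_features(), rt_max_s=220.0)
    out = tmp_path_factory.mktemp("defect_campaign")
    truth = write_campaign(spec, out, force=True)
    return spec, out, truth


@pytest.fixture(scope="session")
def clean_outcome(clean_campaign_dir):
    """The clean campaign screened end-to-end with RIA enabled."""
    from lcqc.io_formats import read_sequence_csv
    from lcqc.pipeline import ScreenParams, screen

    spec, out, _ = clean_campaign_dir
    entries = []
    for s in spec.sequences:
        entries.extend(read_sequence_csv(out / f"{s.name}.csv"))
    return screen(entries, targets_for(spec.features), ScreenParams(compute_ria=True))
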