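"""Shared fixtures: small synthetic cohorts processed through the QC chain."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from connfuse import (
    CohortConfig,
    EdgeIndex,
    correct_functional,
    corrected_volumes,
    functional_network,
    preprocess_subject,
    simulate_cohort,
)
from connfuse.cohort_sim import DEFAULT_PLANTED_EDGES, cohort_arrays


def small_planted_config(seed: int = 7, **overrides) -> CohortConfig:
    """20/20 subjects, 30 regions, strong planted effects in both modalities."""
    base = dict(
        n_group_A=20,
        n_group_B=20,
        n_regions=30,
        n_volumes=120,
        planted_edges=((3, 7, -0.25, 0.25, 0.2), (5, 9, -0.25, 0.25, 0.2)),
        structural_effect=(
            (3, 7, 0.1, 0.6), (5, 9, 0.1, 0.6), (5, 3, 0.5, 0.5),
            (7, 5, 0.5, 0.5), (9, 7, 0.5, 0.5), (9, 3, 0.5, 0.5),
        ),
        episode_counts={"depressive": 8, "manic": 5, "remission": 7},
        seed=seed,
    )
    base.update(overrides)
    return CohortConfig(**base)


def processed_cohort(config: CohortConfig):
    """Simulate and run the full QC + connectome chain; returns
    (labels, corrected volumes, corrected functional features, edge index,
    subjects)."""
    subjects = simulate_cohort(config)
    idx = EdgeIndex(config.n_regions)
    clean = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in subjects:
            res = preprocess_subject(
                s.roi_timeseries,
                s.motion_params,
                s.nuisance_signals,
                tr_seconds=config.tr_seconds,
            )
            clean.append(res.timeseries)
    labels, vols, covs = cohort_arrays(subjects)
    vc = corrected_volumes(vols, covs)
    fc = correct_functional(
        np.vstack([functional_network(ts, idx) for ts in clean]), covs
    )
    return labels, vc, fc, idx, subjects


@pytest.fixture(scope="session")
def planted_cohort():
    return processed_cohort(small_planted_config())


@pytest.fixture(scope="session")
def edge_index_90():
    return EdgeIndex(90)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
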