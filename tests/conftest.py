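"""Shared fixtures: small hand partitions and session-scoped synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from gradientscope import CohortSpec, NetworkPartition, RunConfig, simulate_cohort
from gradientscope.pipeline import analyze_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def part6():
    """Six parcels over three networks (2, 2, 2)."""
    return NetworkPartition(
        parcel_ids=tuple(f"p{i}" for i in range(6)),
        network_of=("A", "A", "B", "B", "C", "C"),
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """A small cohort with a strong planted trait–expansion effect."""
    spec = CohortSpec(n_subjects=60, n_parcels=100, planted_spearman=0.7,
                      n_timepoints=60, n_voxels=40, seed=42)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def planted_results(planted_cohort):
    """Full pipeline output (reports + grid) for the planted cohort."""
    c = planted_cohort
    return analyze_cohort(c.matrices, c.partition, c.participants, RunConfig(),
                          keep_subject_gradients=True)


@pytest.fixture(scope="session")
def planted_gradients(planted_results):
    return planted_results.subject_gradients
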