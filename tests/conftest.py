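"""Shared fixtures: synthetic datasets and LEiDA products reused across tests.

Everything is generated programmatically from fixed seeds; the expensive
artifacts (the full-size two-condition ensemble and its clustering) are
session-scoped so they are computed once.
"""

from __future__ import annotations

import numpy as np
import pytest

from pmspace.leida import (
    bandpass_filter,
    cluster_eigenvectors,
    compute_pms,
    instantaneous_phase,
    pool_eigenvectors,
)
from pmspace.synthetic import (
    SyntheticScenario,
    make_structural_connectivity,
    make_two_condition_dataset,
)


@pytest.fixture(scope="session")
def default_scenario_obj() -> SyntheticScenario:
    """The packaged study-scale scenario: 116 parcels, 20 subjects, 350 TRs,
    rest-like G = 0.04 vs meditation-like G = 0.09."""
    return SyntheticScenario()


@pytest.fixture(scope="session")
def default_sc(default_scenario_obj):
    return make_structural_connectivity(
        default_scenario_obj.n_parcels, seed=default_scenario_obj.sc_seed
    )


@pytest.fixture(scope="session")
def default_dataset(default_scenario_obj, default_sc):
    return make_two_condition_dataset(default_scenario_obj, default_sc)


@pytest.fixture(scope="session")
def default_filtered(default_dataset):
    return {k: bandpass_filter(ts) for k, ts in sorted(default_dataset.items())}


@pytest.fixture(scope="session")
def default_pool(default_filtered):
    return pool_eigenvectors(
        [instantaneous_phase(f) for f in default_filtered.values()]
    )


@pytest.fixture(scope="session")
def cluster_k3(default_pool):
    return cluster_eigenvectors(default_pool, k=3, seed=0, n_replicates=10)


@pytest.fixture(scope="session")
def pms_by_condition(cluster_k3):
    return {c: compute_pms(cluster_k3, c) for c in ("rest", "meditation")}


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    """A reduced scenario for fast pipeline-level tests (formulas unchanged)."""
    return SyntheticScenario(
        n_parcels=20, n_subjects=6, n_timepoints=120, sc_seed=3, sim_seed=5
    )


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    sc = make_structural_connectivity(small_scenario.n_parcels, seed=small_scenario.sc_seed)
    return make_two_condition_dataset(small_scenario, sc), sc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
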