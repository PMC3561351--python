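"""Shared fixtures: deterministic synthetic cohorts exercising each pipeline stage."""

import itertools

import numpy as np
import pytest

from psfnet.synthcohort import CohortSpec, generate_cohort


def recovery_spec() -> CohortSpec:
    """Planted 6-region clique over singleton regions; two tight base groups.

    Designed so D+ recovery of the planted edges is near-perfect while
    every non-planted pair is either deterministic (within base groups)
    or exchangeable noise.
    """
    clique = range(23, 29)
    return CohortSpec(
        n_regions=28,
        base_communities=((1, 2, 3, 4), (5, 6, 7, 8))
        + tuple((i,) for i in range(9, 29)),
        base_coupling=0.3,
        additional_edges=tuple(itertools.combinations(clique, 2)),
        additional_coupling=0.1,
        additional_amplitude=1.5,
        noise_sd=0.1,
        slot_drivers=False,
        seed=7,
    )


def separable_spec() -> CohortSpec:
    """Four tight base communities; cases gain an 8-region cross-community
    clique, lowering their modularity over the low/mid threshold range."""
    return CohortSpec(
        n_regions=20,
        n_samples=400,
        base_communities=tuple(tuple(range(i, i + 5)) for i in (1, 6, 11, 16)),
        base_coupling=0.05,
        additional_edges=tuple(
            itertools.combinations((1, 3, 6, 8, 11, 13, 16, 18), 2)
        ),
        additional_coupling=0.05,
        additional_amplitude=1.0,
        noise_sd=0.05,
        seed=21,
    )


def phase_coupled_spec() -> CohortSpec:
    """Case-only planted dyads with a quarter-cycle lag between endpoints:
    strong phase synchrony, near-zero Pearson correlation."""
    return CohortSpec(
        n_regions=16,
        n_samples=400,
        base_communities=((1, 2, 3, 4), (5, 6, 7, 8))
        + tuple((i,) for i in range(9, 17)),
        base_coupling=0.05,
        additional_edges=((9, 10), (11, 12), (13, 14), (15, 16)),
        additional_coupling=0.05,
        additional_amplitude=2.5,
        noise_sd=0.05,
        seed=31,
    )


def null_spec() -> CohortSpec:
    """No planted structure: case and control cohorts are exchangeable."""
    return CohortSpec(
        n_regions=30, base_coupling=0.3, noise_sd=0.1, slot_drivers=False, seed=3
    )


@pytest.fixture(scope="session")
def recovery_cohort():
    subjects, truth = generate_cohort(recovery_spec(), n_control=20, n_case=20, seed=1)
    return subjects, truth


@pytest.fixture(scope="session")
def separable_cohort():
    subjects, _ = generate_cohort(separable_spec(), n_control=10, n_case=10, seed=5)
    return subjects


@pytest.fixture(scope="session")
def phase_coupled_cohort():
    subjects, _ = generate_cohort(phase_coupled_spec(), n_control=10, n_case=10, seed=9)
    return subjects


@pytest.fixture(scope="session")
def null_cohort():
    subjects, _ = generate_cohort(null_spec(), n_control=20, n_case=20, seed=100)
    return subjects


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
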