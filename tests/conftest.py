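"""Shared fixtures: small synthetic studies cached per test session."""

from __future__ import annotations

import dataclasses

import pytest

from comethnet.simulate import (
    SimConfig,
    simulate_cell_reference,
    simulate_genetic_cohort,
    simulate_methylation_study,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Compact study: quick to generate, still carries the planted structure."""
    return SimConfig(
        n_samples=80,
        n_probes=600,
        module_sizes=(120, 120, 120),
        regions=("SN", "CN"),
        n_genes=600,
        n_celltypes=4,
        n_markers_per_type=60,
        n_overlap_markers=30,
        cells_per_type=80,
        module_gene_pool_size=120,
        n_variants=400,
        n_target=300,
        seed=11,
    )


@pytest.fixture(scope="session")
def meth_study(small_config):
    return simulate_methylation_study(small_config)


@pytest.fixture(scope="session")
def cell_reference(small_config):
    return simulate_cell_reference(small_config)


@pytest.fixture(scope="session")
def genetic_cohort(small_config):
    return simulate_genetic_cohort(small_config)


@pytest.fixture()
def replace():
    """dataclasses.replace as a fixture for terse config tweaks."""
    return dataclasses.replace
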