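"""Shared fixtures: small synthetic graphs and cohorts, all generated at run time."""

from __future__ import annotations

import numpy as np
import pytest

from gradconn import ParcellationInfo, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def parc4() -> ParcellationInfo:
    return ParcellationInfo(
        region_ids=("L_a", "L_b", "R_a", "R_b"),
        hemisphere=("L", "L", "R", "R"),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """24 subjects, 40 regions: fast enough for harness-contract tests."""
    config = SimulationConfig(
        n_subjects=24, n_regions=40, n_template_subjects=5, row_sparsity=0.7
    )
    return simulate_cohort(config, seed=7)


def random_connected_adjacency(rng, n: int, n_subjects: int | None = None):
    """Dense symmetric positive adjacency (hence connected, no zero degree)."""
    shape = (n, n) if n_subjects is None else (n_subjects, n, n)
    a = rng.random(shape) + 0.05
    a = (a + np.swapaxes(a, -1, -2)) / 2
    idx = np.arange(n)
    a[..., idx, idx] = 0.0
    return a
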