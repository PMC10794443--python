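"""Shared fixtures.

The two session-scoped datasets back the scaled-down classification
acceptance checks; they are deliberately smaller than the package's
`reduced_config` so the whole suite fits a desk-scale time budget
(the simulation physics is unchanged, only grid resolution, run length
and vertex cap are reduced).
"""

from __future__ import annotations

import numpy as np
import pytest

from spiketopo import ExperimentConfig, build_dataset

# spec'd reduced world minus the topological measures: full 0.01 grid,
# 5 replicates per g plus 100 extra critical runs, baseline features only.
BASELINE_CFG = ExperimentConfig(
    N=200, T_total=60_000, T_transient=5_000,
    replicates=5, critical_replicates=100, measures=(), master_seed=0,
)

# coarser grid for the topological pipeline (Pearson + SPIKE-distance,
# vertex cap 60) used by the Betti-feature classification and trend checks.
TOPO_CFG = ExperimentConfig(
    N=200, T_total=60_000, T_transient=5_000,
    g_step=0.05, replicates=4, critical_replicates=0,
    vertex_cap=60, measures=("pearson", "spike_distance"), master_seed=0,
)


@pytest.fixture(scope="session")
def baseline_dataset():
    """405 simulations over the full g grid, baseline features only."""
    return build_dataset(BASELINE_CFG)


@pytest.fixture(scope="session")
def topo_dataset():
    """52 simulations on a 0.05 grid with Pearson and SPIKE-distance
    Betti-curve features."""
    return build_dataset(TOPO_CFG)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
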