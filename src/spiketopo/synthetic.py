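"""Synthetic inputs for every pipeline stage: toy spike trains, toy
dissimilarity matrices with analytically known homology, and the
experiment configurations (reduced desk scale and full scale).

Expected outputs quoted in tests for these generators come from closed
forms or brute-force oracles, never from the code under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dissimilarity import DissimilarityMatrix, MEASURES
from .trains import SpikeTrainSet

__all__ = [
    "make_poisson_trains",
    "make_synchronous_trains",
    "make_cycle_matrix",
    "make_cluster_matrix",
    "ExperimentConfig",
    "reduced_config",
    "paper_scale_config",
]


def make_poisson_trains(n: int, rate: float, duration: float,
                        seed: int = 0) -> SpikeTrainSet:
    """Independent homogeneous Poisson trains.

    ``rate`` is in spikes/s, ``duration`` in ms.
    """
    if n < 1:
        raise ValueError("need at least one train")
    if rate <= 0 or duration <= 0:
        raise ValueError("rate and duration must be positive")
    rng = np.random.default_rng(seed)
    trains = []
    for _ in range(n):
        count = rng.poisson(rate * duration / 1000.0)
        trains.append(np.sort(rng.uniform(0.0, duration, size=count)))
    return SpikeTrainSet(trains=trains, t_start=0.0, t_end=duration)


def make_synchronous_trains(n: int, base_rate: float, jitter_ms: float,
                            duration: float = 10_000.0,
                            seed: int = 0) -> SpikeTrainSet:
    """A mother Poisson train copied into ``n`` children with Gaussian jitter.

    ``jitter_ms = 0`` gives identical trains; small jitter produces the
    regime where the adaptive-window SPIKE measures still see synchrony
    but binned Pearson correlation decays.
    """
    if jitter_ms < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    count = rng.poisson(base_rate * duration / 1000.0)
    mother = np.sort(rng.uniform(0.0, duration, size=count))
    trains = []
    for _ in range(n):
        child = mother + (rng.normal(0.0, jitter_ms, size=mother.size)
                          if jitter_ms > 0 else 0.0)
        trains.append(np.sort(np.clip(child, 0.0, duration)))
    return SpikeTrainSet(trains=trains, t_start=0.0, t_end=duration)


def make_cycle_matrix(n: int, r_within: float, r_across: float) -> DissimilarityMatrix:
    """n points on a ring: adjacent pairs at ``r_within``, all others at
    ``r_across``.  Known homology for n >= 4: a single 1-cycle born at
    ``r_within`` and filled at ``r_across``."""
    if n < 3:
        raise ValueError("a cycle needs at least 3 points")
    if not 0 <= r_within < r_across <= 1:
        raise ValueError("need 0 <= r_within < r_across <= 1")
    M = np.full((n, n), r_across)
    np.fill_diagonal(M, 0.0)
    for i in range(n):
        j = (i + 1) % n
        M[i, j] = M[j, i] = r_within
    return DissimilarityMatrix(M=M, measure="synthetic_cycle",
                               vertex_ids=np.arange(n))


def make_cluster_matrix(sizes, d_within: float, d_between: float) -> DissimilarityMatrix:
    """Block matrix of convex clusters: beta_0 drops from sum(sizes) to
    len(sizes) at ``d_within`` and to 1 at ``d_between``; no 1-cycles."""
    sizes = list(sizes)
    if not sizes or any(s < 1 for s in sizes):
        raise ValueError("need at least one non-empty cluster")
    if not 0 <= d_within < d_between <= 1:
        raise ValueError("need 0 <= d_within < d_between <= 1")
    n = sum(sizes)
    M = np.full((n, n), d_between)
    start = 0
    for s in sizes:
        M[start:start + s, start:start + s] = d_within
        start += s
    np.fill_diagonal(M, 0.0)
    return DissimilarityMatrix(M=M, measure="synthetic_clusters",
                               vertex_ids=np.arange(n))


# ---------------------------------------------------------------------------
# experiment configuration


@dataclass(frozen=True)
class ExperimentConfig:
    """Every scale knob of the simulate -> features -> classify pipeline."""

    N: int = 200
    p: float = 0.8
    q: float = 0.2
    J: float = 10.0
    Gamma: float = 0.2
    mu: float = 0.0
    theta: float = 1.0
    I_ext: float = 1.0
    g_start: float = 1.20
    g_stop: float = 1.80
    g_step: float = 0.01
    g_critical: float = 1.50
    replicates: int = 5
    critical_replicates: int = 100
    T_total: int = 60_000
    T_transient: int = 5_000
    bin_ms: float = 4.0
    vertex_cap: int | None = 100
    measures: tuple[str, ...] = MEASURES
    eps_max: float = 1.0
    svm_repeats: int = 20
    master_seed: int = 0

    def g_grid(self) -> np.ndarray:
        n = int(round((self.g_stop - self.g_start) / self.g_step)) + 1
        return np.round(self.g_start + self.g_step * np.arange(n), 10)

    def simulation_plan(self) -> list[tuple[float, int]]:
        """(g, replicate_index) for every simulation, grid first then the
        extra critical replicates."""
        plan = [(float(g), r) for g in self.g_grid() for r in range(self.replicates)]
        plan += [(float(self.g_critical), self.replicates + r)
                 for r in range(self.critical_replicates)]
        return plan

    @property
    def n_simulations(self) -> int:
        return len(self.simulation_plan())

    # -- flat key=value round trip ---------------------------------------
    def save(self, path: str | Path) -> None:
        lines = []
        for key, val in asdict(self).items():
            if key == "measures":
                val = ",".join(val)
            elif val is None:
                val = ""
            lines.append(f"{key}={val}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in cls.__dataclass_fields__.values()}  # noqa: F841
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            val = val.strip()
            if key == "measures":
                kwargs[key] = tuple(m for m in val.split(",") if m)
            elif key == "vertex_cap":
                kwargs[key] = None if val == "" else int(val)
            elif key in ("N", "T_total", "T_transient", "replicates",
                         "critical_replicates", "svm_repeats", "master_seed"):
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
        return cls(**kwargs)


def reduced_config(master_seed: int = 0) -> ExperimentConfig:
    """Desk-scale defaults: N=200, 60,000 steps (5,000 transient), 5
    replicates per g plus 100 extra critical replicates, vertex cap 100."""
    return ExperimentConfig(master_seed=master_seed)


def paper_scale_config(master_seed: int = 0) -> ExperimentConfig:
    """The full-scale protocol: N=1000, 10^6 steps (10^4 transient), 10
    replicates per g plus 190 extra critical replicates, no vertex cap."""
    return ExperimentConfig(N=1000, T_total=1_000_000, T_transient=10_000,
                            replicates=10, critical_replicates=190,
                            vertex_cap=None, master_seed=master_seed)
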