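"""Stochastic excitatory/inhibitory integrate-and-fire network with a
mean-field directed-percolation critical point.

The network is fully connected and homogeneous: ``N`` discrete-time
(1 ms per step) stochastic leaky integrate-and-fire units, a fraction
``p`` excitatory with synaptic weight ``J/N`` and a fraction ``q = 1-p``
inhibitory with weight ``W/N = gJ/N``.  The membrane potential of
neuron *i* evolves as

    V_i[t+1] = (mu * V_i[t] + I_ext + J * rho_E[t] * p - W * rho_I[t] * q)
               * (1 - X_i[t])

where ``X_i[t]`` is the Boolean spike indicator, drawn each step as
Bernoulli(Phi(V_i[t+1])) with the piecewise-linear firing function

    Phi(V) = 0                 for V < theta
           = Gamma * (V-theta) for theta <= V <= V_S = theta + 1/Gamma
           = 1                 for V > V_S.

Because the couplings are homogeneous all-to-all, the recurrent input is
identical for every neuron, and one step costs O(N).

With the default parameters the tonic current holds quiescent neurons
exactly at threshold (``I_ext = theta``), so one presynaptic spike raises
the firing probability of every neuron by ``Gamma*J/N`` (excitatory) or
lowers it by ``Gamma*gJ/N`` (inhibitory).  The branching ratio is then
``Gamma * (pJ - qW)``, which crosses 1 at the critical inhibition ratio

    g_c = p/q - (1-mu) / (q * Gamma * J),

equal to 1.5 for the defaults (p=0.8, q=0.2, Gamma=0.2, J=10, mu=0).
Silence is absorbing (Phi(theta)=0); an offline drive re-ignites the
network by forcing one uniformly chosen neuron to spike whenever the
network falls silent, which also delimits neuronal avalanches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "NetworkParams",
    "NetworkState",
    "SpikeRaster",
    "MeanFieldState",
    "phi",
    "critical_point",
    "step",
    "simulate",
    "mean_field_trajectory",
]


@dataclass(frozen=True)
class NetworkParams:
    """Parameters of the E/I network (defaults: the standard simulation set).

    ``g`` is the inhibition ratio W/J, the control parameter of the
    sub-critical (g > g_c) / critical / super-critical (g < g_c) regimes.
    """

    N: int = 1000
    p: float = 0.8
    q: float = 0.2
    J: float = 10.0
    g: float = 1.5
    Gamma: float = 0.2
    mu: float = 0.0
    theta: float = 1.0
    I_ext: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if abs(self.p + self.q - 1.0) > 1e-12:
            raise ValueError("excitatory and inhibitory fractions must sum to 1")
        if self.g < 0:
            raise ValueError("inhibition ratio g must be >= 0")
        if self.Gamma <= 0:
            raise ValueError("firing gain Gamma must be > 0")
        if not 0.0 <= self.mu < 1.0:
            raise ValueError("leakage mu must lie in [0, 1)")

    @property
    def N_E(self) -> int:
        return int(round(self.p * self.N))

    @property
    def N_I(self) -> int:
        return self.N - self.N_E

    @property
    def W(self) -> float:
        """Inhibitory weight W = g*J."""
        return self.g * self.J

    @property
    def V_S(self) -> float:
        """Saturation potential theta + 1/Gamma."""
        return self.theta + 1.0 / self.Gamma

    @property
    def W_bar(self) -> float:
        """Effective coupling pJ - qW."""
        return self.p * self.J - self.q * self.W


@dataclass
class NetworkState:
    """Membrane potentials and spike indicators at one time step."""

    V: np.ndarray
    X: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.X = np.asarray(self.X, dtype=bool)
        if self.V.shape != self.X.shape:
            raise ValueError("V and X must have the same shape")


@dataclass
class SpikeRaster:
    """Spike events of one simulation, at 1 ms resolution.

    ``events`` is an (n_spikes, 2) integer array of (neuron_id, time_step)
    pairs sorted by time then neuron; ``drive_times`` lists the steps at
    which the offline drive forced a spike.  Times are re-indexed to start
    at 0 after transient removal.
    """

    N: int
    T: int
    events: np.ndarray
    params: NetworkParams | None = None
    drive_times: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.int64).reshape(-1, 2)
        self.drive_times = np.asarray(self.drive_times, dtype=np.int64)
        if self.events.size:
            if self.events[:, 0].min() < 0 or self.events[:, 0].max() >= self.N:
                raise ValueError("neuron ids out of range")
            if self.events[:, 1].min() < 0 or self.events[:, 1].max() >= self.T:
                raise ValueError("spike times out of range")

    @property
    def n_spikes(self) -> int:
        return int(self.events.shape[0])

    def activity(self) -> np.ndarray:
        """Population spike count A[t] for every recorded step."""
        return np.bincount(self.events[:, 1], minlength=self.T)

    def spike_times(self) -> list[np.ndarray]:
        """Per-neuron sorted spike-time arrays (ms)."""
        order = np.lexsort((self.events[:, 1], self.events[:, 0]))
        ev = self.events[order]
        out: list[np.ndarray] = []
        bounds = np.searchsorted(ev[:, 0], np.arange(self.N + 1))
        for i in range(self.N):
            out.append(ev[bounds[i]:bounds[i + 1], 1].astype(float))
        return out

    # -- plain-text event-list round trip ---------------------------------
    def save(self, path: str | Path) -> None:
        """Write a ``neuron_id<TAB>time_ms`` event list with a # header."""
        lines = [f"# N={self.N}", f"# T={self.T}"]
        if self.params is not None:
            for key in ("N", "p", "q", "J", "g", "Gamma", "mu", "theta", "I_ext", "seed"):
                lines.append(f"# param_{key}={getattr(self.params, key)}")
        lines.append("# drive_times=" + ",".join(map(str, self.drive_times.tolist())))
        for nid, t in self.events:
            lines.append(f"{nid}\t{t}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SpikeRaster":
        header: dict[str, str] = {}
        rows: list[tuple[int, int]] = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                header[key.strip()] = val.strip()
            else:
                a, b = line.split("\t")
                rows.append((int(a), int(b)))
        params = None
        if "param_N" in header:
            params = NetworkParams(
                N=int(header["param_N"]), p=float(header["param_p"]),
                q=float(header["param_q"]), J=float(header["param_J"]),
                g=float(header["param_g"]), Gamma=float(header["param_Gamma"]),
                mu=float(header["param_mu"]), theta=float(header["param_theta"]),
                I_ext=float(header["param_I_ext"]), seed=int(header["param_seed"]),
            )
        drive = header.get("drive_times", "")
        drive_times = np.array([int(x) for x in drive.split(",") if x], dtype=np.int64)
        return cls(
            N=int(header["N"]), T=int(header["T"]),
            events=np.array(rows, dtype=np.int64).reshape(-1, 2),
            params=params, drive_times=drive_times,
        )


@dataclass
class MeanFieldState:
    """One step of the deterministic population (mean-field) map."""

    V_E: float
    V_I: float
    rho_E: float
    rho_I: float
    W_bar: float
    W_bar_c: float
    g_c: float

    @property
    def rho(self) -> float:
        """Excitatory firing fraction (the two populations receive identical
        input, so rho_E = rho_I whenever they start equal)."""
        return self.rho_E


def phi(V, params: NetworkParams):
    """Piecewise-linear firing probability Phi(V).

    Returns 0 below threshold, ``Gamma*(V-theta)`` on the linear branch and
    1 above the saturation potential.  Accepts scalars or arrays.
    """
    V = np.asarray(V, dtype=float)
    out = np.clip((V - params.theta) * params.Gamma, 0.0, 1.0)
    return out if out.ndim else float(out)


def critical_point(params: NetworkParams) -> tuple[float, float]:
    """Mean-field critical point (W_bar_c, g_c).

    W_bar_c = (1-mu)/Gamma and g_c = p/q - (1-mu)/(q*Gamma*J); the network
    is super-critical for g < g_c and sub-critical for g > g_c.
    """
    if params.q == 0 or params.J == 0:
        raise ValueError("critical point undefined for q=0 or J=0")
    W_bar_c = (1.0 - params.mu) / params.Gamma
    g_c = params.p / params.q - (1.0 - params.mu) / (params.q * params.Gamma * params.J)
    return W_bar_c, g_c


def _recurrent_input(X: np.ndarray, params: NetworkParams) -> float:
    """Common recurrent drive (J*nE - W*nI)/N; identical for all neurons."""
    nE = int(X[: params.N_E].sum())
    nI = int(X[params.N_E:].sum())
    return (params.J * nE - params.W * nI) / params.N


def step(state: NetworkState, params: NetworkParams, rng: np.random.Generator) -> NetworkState:
    """Advance the network one time step.

    The potential update applies the leak, the tonic current and the
    homogeneous recurrent input, with the (1 - X) factor resetting neurons
    that just fired; new spikes are independent Bernoulli draws from
    Phi(V[t+1]).
    """
    if state.V.shape[0] != params.N:
        raise ValueError("state dimension does not match params.N")
    rec = _recurrent_input(state.X, params)
    V_new = (params.mu * state.V + params.I_ext + rec) * (~state.X)
    X_new = rng.random(params.N) < phi(V_new, params)
    return NetworkState(V=V_new, X=X_new, t=state.t + 1)


def initial_state(params: NetworkParams, rng: np.random.Generator,
                  p_active: float = 0.1) -> NetworkState:
    """V = 0 everywhere; each neuron initially active with prob ``p_active``."""
    V = np.zeros(params.N)
    X = rng.random(params.N) < p_active
    return NetworkState(V=V, X=X, t=0)


def simulate(params: NetworkParams, T_total: int, T_transient: int = 10_000,
             rng: np.random.Generator | None = None,
             init_active: float = 0.1) -> SpikeRaster:
    """Run the network for ``T_total`` steps and return the post-transient raster.

    Whenever the stochastic draw leaves the whole network silent, the
    offline drive forces one uniformly chosen neuron to spike at that same
    step (recorded in ``drive_times``), so every recorded step has at least
    one spike.  Events with t >= T_transient are kept, re-indexed to 0.
    """
    if T_total <= 0:
        raise ValueError("T_total must be positive")
    if not 0 <= T_transient < T_total:
        raise ValueError("need 0 <= T_transient < T_total")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    N, NE = params.N, params.N_E
    mu, I_ext, J, W = params.mu, params.I_ext, params.J, params.W
    theta, Gamma = params.theta, params.Gamma

    state = initial_state(params, rng, p_active=init_active)
    V, X = state.V, state.X

    drive: list[int] = []
    T_rec = T_total - T_transient
    # dense (T_rec, N) buffer up to ~400 MB; sparse event lists beyond
    dense = T_rec * N <= 400_000_000
    Xbuf = np.zeros((T_rec, N), dtype=bool) if dense else None
    ev_n: list[np.ndarray] = []
    ev_t: list[np.ndarray] = []

    # Uniform draws are consumed in fixed order (one row of N+1 per step:
    # N for the Bernoulli spikes, one reserved for the drive-neuron choice),
    # so a given rng state yields a bit-identical raster on either branch.
    chunk = 2048
    t = 0
    while t < T_total:
        csize = min(chunk, T_total - t)
        U = rng.random((csize, N + 1))
        for k in range(csize):
            rec = (J * np.count_nonzero(X[:NE]) - W * np.count_nonzero(X[NE:])) / N
            if mu == 0.0:
                # every non-refractory neuron sits at the same potential
                prob = min(max((I_ext + rec - theta) * Gamma, 0.0), 1.0)
                X = (U[k, :N] < prob) & ~X if prob > 0.0 else np.zeros(N, dtype=bool)
            else:
                V = (mu * V + I_ext + rec) * (~X)
                prob_v = np.clip((V - theta) * Gamma, 0.0, 1.0)
                X = U[k, :N] < prob_v
            if not X.any():
                X = np.zeros(N, dtype=bool)
                X[int(U[k, N] * N)] = True
                if t >= T_transient:
                    drive.append(t - T_transient)
            if t >= T_transient:
                if dense:
                    Xbuf[t - T_transient] = X
                else:
                    idx = np.flatnonzero(X)
                    ev_n.append(idx)
                    ev_t.append(np.full(idx.size, t - T_transient, dtype=np.int64))
            t += 1

    if dense:
        tt, nn = np.nonzero(Xbuf)
    else:
        nn = np.concatenate(ev_n) if ev_n else np.empty(0, dtype=np.int64)
        tt = np.concatenate(ev_t) if ev_t else np.empty(0, dtype=np.int64)
    events = np.column_stack([nn.astype(np.int64), tt.astype(np.int64)])
    return SpikeRaster(N=N, T=T_rec, events=events, params=params,
                       drive_times=np.array(drive, dtype=np.int64))


def mean_field_trajectory(params: NetworkParams, rho0: float, T: int,
                          rho0_I: float | None = None) -> list[MeanFieldState]:
    """Iterate the deterministic population map for ``T`` steps.

    The quiescent-neuron potential evolves as
    ``V[t+1] = mu*V[t] + I_ext + p*J*rho_E[t] - q*W*rho_I[t]`` and the
    firing fractions as ``rho[t+1] = (1 - rho[t]) * Phi(V[t+1])``: the
    (1 - rho) factor accounts for the just-reset neurons, which sit at
    V = 0 and cannot fire (Phi(0) = 0 for theta >= 0).  This is the exact
    N -> infinity limit of the homogeneous network and reproduces the
    critical point of :func:`critical_point`.
    """
    if not 0.0 <= rho0 <= 1.0:
        raise ValueError("rho0 must lie in [0, 1]")
    rho_E = float(rho0)
    rho_I = float(rho0 if rho0_I is None else rho0_I)
    V_E = V_I = params.I_ext
    W_bar_c, g_c = critical_point(params)
    traj: list[MeanFieldState] = []
    for _ in range(T):
        rec = params.p * params.J * rho_E - params.q * params.W * rho_I
        V_E = params.mu * V_E + params.I_ext + rec
        V_I = params.mu * V_I + params.I_ext + rec
        rho_E = (1.0 - rho_E) * phi(V_E, params)
        rho_I = (1.0 - rho_I) * phi(V_I, params)
        traj.append(MeanFieldState(V_E=V_E, V_I=V_I, rho_E=rho_E, rho_I=rho_I,
                                   W_bar=params.W_bar, W_bar_c=W_bar_c, g_c=g_c))
    return traj
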