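"""Recurrent ring model with firing-rate homeostasis via structural rewiring.

A ring of simple stochastic spiking neurons (80% excitatory by default).
Each activity step, neuron i receives

    X_i = sum_j sign_j * C[i, j] * s_j + Poisson(lambda_ext)

where ``C[i, j]`` counts directed synapses from j to i and sign_j is +1/-1
for excitatory/inhibitory presynaptic partners, and fires with probability
F(X_i) = 1 / (1 + exp(-beta * (X_i - theta))).  Every ``T`` activity steps a
morphological step adjusts synapse counts toward the homeostatic target
firing probability 0.5: with dF = mean(F over the last ``window`` steps) - 0.5,

    dI_i = nu * dF_i * I_i      (and analogously for out-degree)

synapses are removed when the neuron fires above target and formed (with a
Gaussian ring-distance kernel) when below.  Fractional changes accumulate in
per-neuron residuals; each synapse marked for removal is actually deleted
with probability ``p_del``.  Network disability is the across-neuron
variance of the time-averaged firing probability of alive neurons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .errors import ConfigurationError, UsageError
from .lesion import LesionSchedule, apply_removal, removal_events
from .results import DisabilityTrace

__all__ = [
    "HomeoParams",
    "HomeostasisState",
    "build_ring",
    "activity_step",
    "morphological_step",
    "connection_change",
    "disability",
    "run_homeostasis_trial",
]


@dataclass(frozen=True)
class HomeoParams:
    """Parameters of the homeostasis model.

    Defaults are the reference set: 100 neurons, morphological period T=100
    activity steps, firing threshold theta=500, sigmoid steepness beta=0.002,
    deletion probability p_del=0.1, homeostatic rate nu=0.005, Poisson
    external-input rate lambda_ext=30, 80% excitatory neurons, averaging
    window 1000 activity steps.  ``init_indegree=940`` puts the expected
    drive at target rate near threshold (0.5*940 + 30 = 500); ``kernel_sigma``
    sets how strongly new synapses prefer near ring neighbours.
    """

    n_nodes: int = 100
    T: int = 100
    theta: float = 500.0
    beta: float = 0.002
    p_del: float = 0.1
    nu: float = 0.005
    lambda_ext: float = 30.0
    frac_excit: float = 0.8
    window: int = 1000
    init_indegree: int = 940
    kernel_sigma: float = 10.0

    def validate(self) -> None:
        if self.n_nodes <= 1:
            raise ConfigurationError(f"n_nodes must be > 1, got {self.n_nodes}")
        if self.T <= 0:
            raise ConfigurationError(f"T must be > 0, got T={self.T}")
        if not 0.0 <= self.p_del <= 1.0:
            raise ConfigurationError(f"p_del must lie in [0, 1], got {self.p_del}")
        if self.nu < 0:
            raise ConfigurationError(f"nu must be >= 0, got nu={self.nu}")
        if self.lambda_ext < 0:
            raise ConfigurationError(
                f"lambda_ext must be >= 0, got {self.lambda_ext}"
            )
        if not 0.0 <= self.frac_excit <= 1.0:
            raise ConfigurationError(
                f"frac_excit must lie in [0, 1], got {self.frac_excit}"
            )
        if self.window <= 0:
            raise ConfigurationError(f"window must be > 0, got {self.window}")
        if self.init_indegree < 0:
            raise ConfigurationError(
                f"init_indegree must be >= 0, got {self.init_indegree}"
            )
        if self.kernel_sigma <= 0:
            raise ConfigurationError(
                f"kernel_sigma must be > 0, got {self.kernel_sigma}"
            )


@dataclass
class HomeostasisState:
    """Mutable state: synapse-count matrix C (C[i, j] = synapses j -> i,
    stored as integer-valued float64 for fast matvecs), excitatory/alive
    flags, current binary states, a circular buffer of firing probabilities
    over the averaging window, and fractional connection-change residuals."""

    C: NDArray[np.float64]
    excitatory: NDArray[np.bool_]
    alive: NDArray[np.bool_]
    s: NDArray[np.int8]
    F_buf: NDArray[np.float64]
    buf_pos: int = 0
    buf_count: int = 0
    res_in: NDArray[np.float64] = None
    res_out: NDArray[np.float64] = None
    kernel: NDArray[np.float64] = None
    t_act: int = 0

    @property
    def n(self) -> int:
        return self.alive.shape[0]

    @property
    def sign(self) -> NDArray[np.float64]:
        return np.where(self.excitatory, 1.0, -1.0)

    def indegree(self) -> NDArray[np.float64]:
        return self.C.sum(axis=1)

    def outdegree(self) -> NDArray[np.float64]:
        return self.C.sum(axis=0)

    def fbar(self) -> NDArray[np.float64]:
        """Per-neuron mean firing probability over the filled part of the
        window (averages over what exists early in a run)."""
        if self.buf_count == 0:
            raise UsageError("firing-probability history is empty")
        return self.F_buf[: self.buf_count].mean(axis=0)

    def push_F(self, F: NDArray[np.float64]) -> None:
        self.F_buf[self.buf_pos] = F
        self.buf_pos = (self.buf_pos + 1) % self.F_buf.shape[0]
        self.buf_count = min(self.buf_count + 1, self.F_buf.shape[0])

    def kill(self, nodes: NDArray[np.intp]) -> None:
        """Disconnect neurons entirely and bar them from future rewiring."""
        self.alive[nodes] = False
        self.C[nodes, :] = 0.0
        self.C[:, nodes] = 0.0
        self.s[nodes] = 0
        self.res_in[nodes] = 0.0
        self.res_out[nodes] = 0.0


def _ring_kernel(n: int, sigma: float) -> NDArray[np.float64]:
    """exp(-d^2 / 2 sigma^2) on ring distance, zero diagonal (no autapses).
    sigma = inf gives a flat kernel (uniform partner choice)."""
    idx = np.arange(n)
    diff = np.abs(idx[:, None] - idx[None, :])
    d = np.minimum(diff, n - diff).astype(np.float64)
    if math.isinf(sigma):
        K = np.ones((n, n))
    else:
        K = np.exp(-(d**2) / (2.0 * sigma**2))
    np.fill_diagonal(K, 0.0)
    return K


def build_ring(params: HomeoParams, seed) -> HomeostasisState:
    """Construct the initial ring: a random subset of ceil(frac_excit * n)
    neurons flagged excitatory, each neuron given ``init_indegree`` input
    synapses with presynaptic partners drawn from the ring-distance kernel,
    random initial binary states."""
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = params.n_nodes
    excitatory = np.zeros(n, dtype=bool)
    n_exc = math.ceil(params.frac_excit * n)
    excitatory[rng.permutation(n)[:n_exc]] = True

    kernel = _ring_kernel(n, params.kernel_sigma)
    C = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        p = kernel[i] / kernel[i].sum()
        partners = rng.choice(n, size=params.init_indegree, p=p)
        np.add.at(C[i], partners, 1.0)

    s = rng.integers(0, 2, size=n).astype(np.int8)
    return HomeostasisState(
        C=C,
        excitatory=excitatory,
        alive=np.ones(n, dtype=bool),
        s=s,
        F_buf=np.zeros((params.window, n), dtype=np.float64),
        res_in=np.zeros(n, dtype=np.float64),
        res_out=np.zeros(n, dtype=np.float64),
        kernel=kernel,
    )


def firing_probability(X, params: HomeoParams):
    """F(X) = 1 / (1 + exp(-beta * (X - theta)))."""
    return 1.0 / (1.0 + np.exp(-params.beta * (np.asarray(X, dtype=np.float64) - params.theta)))


def activity_step(
    state: HomeostasisState, params: HomeoParams, rng: np.random.Generator
) -> HomeostasisState:
    """One activity update: summed signed synaptic drive plus Poisson
    external input, sigmoid firing probability, Bernoulli state update.
    Dead neurons stay silent with F recorded as 0 (they are excluded from
    all statistics via the alive mask)."""
    drive = state.C @ (state.s * state.sign)
    X = drive + rng.poisson(params.lambda_ext, size=state.n)
    F = firing_probability(X, params)
    F[~state.alive] = 0.0
    new_s = (rng.random(state.n) < F) & state.alive
    state.s = new_s.astype(np.int8)
    state.push_F(F)
    state.t_act += 1
    return state


def connection_change(nu: float, dFbar, degree):
    """Homeostatic connection-change magnitude nu * dFbar * degree.

    Positive values mean the neuron is above the target rate and sheds
    synapses; negative values mean it is below target and grows them.  The
    magnitude is proportional to the deviation from homeostasis, so recovery
    accelerates with disability (the opposite of the three-layer model's
    disability-dependent learning rate)."""
    return nu * np.asarray(dFbar, dtype=np.float64) * np.asarray(degree, dtype=np.float64)


def _sample_existing(rng: np.random.Generator, counts: NDArray[np.float64]) -> int:
    """Pick one existing synapse uniformly from a count vector."""
    total = counts.sum()
    return int(rng.choice(len(counts), p=counts / total))


def morphological_step(
    state: HomeostasisState, params: HomeoParams, rng: np.random.Generator
) -> HomeostasisState:
    """One structural-plasticity update toward the target rate 0.5.

    For each alive neuron the signed change nu * dFbar * degree accumulates
    in input- and output-side residuals; the integer part is realized.
    Above-target neurons mark synapses for removal (each deleted with
    probability p_del, sampled uniformly from their existing synapses);
    below-target neurons form new synapses with partners drawn from the
    ring-distance kernel among alive neurons.  Counts never go negative and
    dead neurons are never touched.  Input-side passes run before
    output-side passes, in neuron order."""
    fbar = state.fbar()
    dF = fbar - 0.5
    alive = state.alive
    state.res_in[alive] += connection_change(params.nu, dF[alive], state.indegree()[alive])
    state.res_out[alive] += connection_change(params.nu, dF[alive], state.outdegree()[alive])

    alive_idx = np.flatnonzero(alive)
    for i in alive_idx:
        state.res_in[i] = _realize(state, params, rng, int(i), axis="in")
    for j in alive_idx:
        state.res_out[j] = _realize(state, params, rng, int(j), axis="out")
    return state


def _realize(
    state: HomeostasisState,
    params: HomeoParams,
    rng: np.random.Generator,
    node: int,
    axis: str,
) -> float:
    """Realize the integer part of one neuron's residual on one side of C."""
    res = state.res_in[node] if axis == "in" else state.res_out[node]
    counts = state.C[node, :] if axis == "in" else state.C[:, node]
    if res >= 1.0:  # above target: shed synapses
        k = int(res)
        res -= k
        for _ in range(k):
            if counts.sum() <= 0:
                break
            victim = _sample_existing(rng, counts)
            if rng.random() < params.p_del:
                counts[victim] -= 1.0
    elif res <= -1.0:  # below target: grow synapses
        g = int(-res)
        res += g
        weights = (state.kernel[node] if axis == "in" else state.kernel[:, node]).copy()
        weights[~state.alive] = 0.0
        total = weights.sum()
        if total > 0:
            partners = rng.choice(state.n, size=g, p=weights / total)
            if axis == "in":
                np.add.at(state.C[node], partners, 1.0)
            else:
                np.add.at(state.C[:, node], partners, 1.0)
    return res


def disability(state: HomeostasisState) -> float:
    """Network disability: population variance, across alive neurons, of the
    per-neuron mean firing probability over the averaging window.  Bounded
    by 0.25 for probabilities in [0, 1]."""
    if not state.alive.any():
        raise UsageError("disability is undefined with no alive neurons")
    fbar = state.fbar()[state.alive]
    return float(np.var(fbar))


def run_homeostasis_trial(
    params: HomeoParams,
    schedule: LesionSchedule,
    total_morph_steps: int,
    seed,
) -> DisabilityTrace:
    """Full trial: alternate T activity steps with one morphological step for
    ``total_morph_steps`` morphological steps, applying scheduled removals at
    their morphological times (before that period's activity), and recording
    disability, alive count, mean firing probability and total synapse count
    at every morphological step.

    Schedule times (start_time, irt) count morphological steps; the
    reference experiments start injury at morphological step 2700 so the
    network reaches homeostasis first.
    """
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = build_ring(params, rng)
    schedule = schedule.resolve_start_index(rng, params.n_nodes)
    events = removal_events(schedule, params.n_nodes)
    if events and events[-1][0] >= total_morph_steps:
        raise UsageError(
            f"last removal at morphological step {events[-1][0]} does not fit in "
            f"total_morph_steps={total_morph_steps}"
        )
    by_time: dict[int, list[tuple[int, ...]]] = {}
    for t_ev, nodes in events:
        by_time.setdefault(t_ev, []).append(nodes)

    first_t = events[0][0] if events else None
    last_t = events[-1][0] if events else None
    times, dis, alive_count, mean_F, total_syn, phase = [], [], [], [], [], []
    for ms in range(total_morph_steps):
        for nodes in by_time.get(ms, ()):
            apply_removal(state, np.asarray(nodes, dtype=np.intp))
        for _ in range(params.T):
            activity_step(state, params, rng)
        morphological_step(state, params, rng)
        times.append(ms)
        dis.append(disability(state))
        alive_count.append(int(state.alive.sum()))
        mean_F.append(float(state.fbar()[state.alive].mean()))
        total_syn.append(float(state.C.sum()))
        if first_t is None or ms < first_t:
            phase.append("pre")
        elif ms <= last_t:
            phase.append("lesion")
        else:
            phase.append("recovery")

    return DisabilityTrace(
        times=np.asarray(times),
        disability=np.asarray(dis),
        events=events,
        phase=np.asarray(phase),
        extras={
            "alive_count": np.asarray(alive_count),
            "mean_F": np.asarray(mean_F),
            "total_synapses": np.asarray(total_syn),
        },
        meta={
            "model": "homeostasis",
            "time_column": "morph_step",
            "schedule": schedule,
            "total_morph_steps": total_morph_steps,
            "disability_definition": "variance across alive neurons of per-neuron "
            "time-mean F over the averaging window",
        },
    )
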