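"""Three-ring feed-forward lesion model.

Three rings of ``N`` binary nodes each (input, middle/processing, output).
Node ``j`` of a layer feeds the inclusive modular neighbourhood
``j - n//2 … j + n//2`` of the next layer, so each node has
``n_effective = 2*(n//2) + 1`` feed-forward connections.  Middle nodes fire
stochastically through a sigmoid of their weighted input; output nodes are
deterministic threshold (Heaviside) units.  A Hebbian-like rule

    dw = eta * (a * s_post * s_pre - b * s_post - c * s_pre)

runs whenever the output disagrees with the desired pattern, with weights
clipped to ``[w_min, w_max]``.  Network disability is the Hamming distance
between actual and desired output.  The learning rate is either fixed or a
smoothly decreasing function of disability that vanishes at a critical
disability ``Hc``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import NDArray

from .errors import ConfigurationError, UsageError

logger = logging.getLogger(__name__)

__all__ = [
    "ThreeLayerParams",
    "EtaPolicy",
    "ThreeLayerState",
    "ring_mask",
    "build_network",
    "random_pattern",
    "middle_step",
    "output_step",
    "hamming",
    "eta_of_H",
    "hebbian_delta",
    "train_step",
    "pre_lesion_train",
]


@dataclass(frozen=True)
class ThreeLayerParams:
    """Parameters of the three-layer model.

    Defaults are the reference parameter set used throughout: N=500 nodes per
    ring, fan-out neighbourhood n=100, thresholds 5.54, sigmoid noise
    amplitude beta=0.25, Hebb constants (a, b, c) = (1.5, 0.5, 0.5) so that
    coincident activity gives +eta/2 and single-sided activity -eta/2, weight
    bounds [0, 10.3], base learning rate 0.01 and learning-rate knee H0=5.
    ``Hc`` (critical disability) is case-dependent and therefore has no
    default; it is required only for the modified learning-rate policy.

    ``init_w_im_high`` / ``init_w_mo_high`` set the upper end of the uniform
    initial-weight distribution per layer.  ``None`` means the package
    default: full range ``w_max`` for input->middle (a saturating relay) and
    ``2*theta_output/n_effective`` for middle->output, which places initial
    output drive at the firing threshold so that training settles in the
    lesion-sensitive regime (see docs/methods.md).
    """

    N: int = 500
    n: int = 100
    theta_ml: float = 5.54
    theta_output: float = 5.54
    beta: float = 0.25
    a: float = 1.5
    b: float = 0.5
    c: float = 0.5
    w_max: float = 10.3
    w_min: float = 0.0
    eta0: float = 0.01
    H0: float = 5.0
    Hc: float | None = None
    active_fraction: float = 0.5
    init_w_im_high: float | None = None
    init_w_mo_high: float | None = None

    @property
    def n_effective(self) -> int:
        """Actual connections per node: the inclusive range j-n//2 … j+n//2."""
        return 2 * (self.n // 2) + 1

    def validate(self) -> None:
        if self.N <= 0:
            raise ConfigurationError(f"N must be positive, got N={self.N}")
        if not 0 < self.n < self.N:
            raise ConfigurationError(
                f"n must satisfy 0 < n < N, got n={self.n}, N={self.N}"
            )
        if self.w_min > self.w_max:
            raise ConfigurationError(
                f"w_min must be <= w_max, got w_min={self.w_min}, w_max={self.w_max}"
            )
        if self.w_min < 0:
            raise ConfigurationError(f"w_min must be >= 0, got w_min={self.w_min}")
        if self.eta0 <= 0:
            raise ConfigurationError(f"eta0 must be > 0, got eta0={self.eta0}")
        if self.H0 < 0:
            raise ConfigurationError(f"H0 must be >= 0, got H0={self.H0}")
        if self.Hc is not None and not self.H0 < self.Hc <= self.N:
            raise ConfigurationError(
                f"Hc must satisfy H0 < Hc <= N, got H0={self.H0}, "
                f"Hc={self.Hc}, N={self.N}"
            )
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ConfigurationError(
                f"active_fraction must lie in [0, 1], got {self.active_fraction}"
            )

    def scaled(self, N: int = 100, n: int = 20) -> "ThreeLayerParams":
        """Proportionally scaled-down variant (default N=100, n=20) used for
        fast experiments; all other parameters unchanged."""
        return replace(self, N=N, n=n)


@dataclass(frozen=True)
class EtaPolicy:
    """Learning-rate law: ``fixed`` (eta = eta0 always) or ``modified``
    (eta decreases smoothly from eta0 to 0 as disability grows from H0 to the
    critical disability Hc)."""

    mode: str = "fixed"
    eta0: float = 0.01
    H0: float = 5.0
    Hc: float | None = None

    def validate(self) -> None:
        if self.mode not in ("fixed", "modified"):
            raise ConfigurationError(
                f"eta mode must be 'fixed' or 'modified', got {self.mode!r}"
            )
        if self.eta0 <= 0:
            raise ConfigurationError(f"eta0 must be > 0, got eta0={self.eta0}")
        if self.mode == "modified":
            if self.Hc is None:
                raise ConfigurationError(
                    "Hc is required when eta mode is 'modified' (case-dependent, "
                    "no default)"
                )
            if not self.H0 < self.Hc:
                raise ConfigurationError(
                    f"modified eta requires H0 < Hc, got H0={self.H0}, Hc={self.Hc}"
                )

    @classmethod
    def fixed(cls, eta0: float = 0.01) -> "EtaPolicy":
        return cls(mode="fixed", eta0=eta0)

    @classmethod
    def modified(cls, eta0: float = 0.01, H0: float = 5.0, Hc: float = 25.0) -> "EtaPolicy":
        return cls(mode="modified", eta0=eta0, H0=H0, Hc=Hc)


@dataclass
class ThreeLayerState:
    """Entire mutable state of the three-layer model.

    ``W_im[i, j]`` is the weight from input node j to middle node i and
    ``W_mo[i, j]`` from middle node j to output node i; both are nonzero only
    on the shared ring-neighbourhood mask.  ``alive`` flags middle nodes;
    dead nodes never fire and their incident weights are zero.
    """

    W_im: NDArray[np.float64]
    W_mo: NDArray[np.float64]
    mask: NDArray[np.bool_]
    alive: NDArray[np.bool_]
    input_pattern: NDArray[np.int8]
    desired_output: NDArray[np.int8]
    t: int = 0

    @property
    def N(self) -> int:
        return self.alive.shape[0]

    def kill(self, nodes: NDArray[np.intp]) -> None:
        """Remove middle nodes: clear alive flags and zero incident weights."""
        self.alive[nodes] = False
        self.W_im[nodes, :] = 0.0
        self.W_mo[:, nodes] = 0.0

    def copy(self) -> "ThreeLayerState":
        return ThreeLayerState(
            W_im=self.W_im.copy(),
            W_mo=self.W_mo.copy(),
            mask=self.mask,
            alive=self.alive.copy(),
            input_pattern=self.input_pattern.copy(),
            desired_output=self.desired_output.copy(),
            t=self.t,
        )


def ring_mask(N: int, n: int) -> NDArray[np.bool_]:
    """Boolean (N, N) connectivity mask: entry (i, j) is True iff the ring
    distance between i and j is at most n//2 (inclusive modular range)."""
    idx = np.arange(N)
    diff = np.abs(idx[:, None] - idx[None, :])
    ring_dist = np.minimum(diff, N - diff)
    return ring_dist <= n // 2


def random_pattern(N: int, active_fraction: float, rng: np.random.Generator) -> NDArray[np.int8]:
    """Random binary pattern with ``round(active_fraction*N)`` active nodes."""
    k = int(round(active_fraction * N))
    pattern = np.zeros(N, dtype=np.int8)
    pattern[rng.choice(N, size=k, replace=False)] = 1
    return pattern


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def build_network(params: ThreeLayerParams, seed) -> ThreeLayerState:
    """Construct a fresh network: masked weights drawn uniformly per layer
    (see ``ThreeLayerParams`` for the per-layer ranges), all middle nodes
    alive, one random input/desired pattern pair with ``active_fraction``
    active nodes.

    ``seed`` may be an int, a ``numpy.random.SeedSequence`` or an existing
    ``Generator`` (which is consumed, enabling streamed composition).
    """
    params.validate()
    rng = _as_rng(seed)
    N = params.N
    mask = ring_mask(N, params.n)

    hi_im = params.w_max if params.init_w_im_high is None else params.init_w_im_high
    hi_mo = (
        2.0 * params.theta_output / params.n_effective
        if params.init_w_mo_high is None
        else params.init_w_mo_high
    )
    W_im = rng.uniform(params.w_min, hi_im, size=(N, N))
    W_mo = rng.uniform(params.w_min, hi_mo, size=(N, N))
    W_im[~mask] = 0.0
    W_mo[~mask] = 0.0
    np.clip(W_im, params.w_min, params.w_max, out=W_im)
    np.clip(W_mo, params.w_min, params.w_max, out=W_mo)

    input_pattern = random_pattern(N, params.active_fraction, rng)
    desired_output = random_pattern(N, params.active_fraction, rng)

    return ThreeLayerState(
        W_im=W_im,
        W_mo=W_mo,
        mask=mask,
        alive=np.ones(N, dtype=bool),
        input_pattern=input_pattern,
        desired_output=desired_output,
    )


def middle_step(
    state: ThreeLayerState, params: ThreeLayerParams, rng: np.random.Generator
) -> NDArray[np.int8]:
    """One stochastic update of the middle layer.

    Each alive node i receives X_i = sum_j W_im[i, j] * input_j and fires
    with probability F(X_i) = 1 / (1 + exp(-beta * (X_i - theta_ml))).
    Dead nodes stay silent.  Exactly N uniform draws are consumed regardless
    of the alive mask, so parallel runs that differ only in lesion schedule
    share a random stream until their states diverge.
    """
    X = state.W_im @ state.input_pattern.astype(np.float64)
    p = 1.0 / (1.0 + np.exp(-params.beta * (X - params.theta_ml)))
    fired = rng.random(state.N) < p
    fired &= state.alive
    return fired.astype(np.int8)


def output_step(
    state: ThreeLayerState,
    middle_states: NDArray[np.int8],
    params: ThreeLayerParams,
) -> NDArray[np.int8]:
    """Deterministic Heaviside output layer: O_i = 1 iff the summed middle
    drive reaches theta_output (a tie at exactly theta counts as firing)."""
    if len(middle_states) != state.N:
        raise UsageError(
            f"middle_states has length {len(middle_states)}, expected {state.N}"
        )
    drive = state.W_mo @ np.asarray(middle_states, dtype=np.float64)
    return (drive >= params.theta_output).astype(np.int8)


def hamming(actual, desired) -> int:
    """Number of positions where two equal-length binary vectors differ."""
    a = np.asarray(actual)
    d = np.asarray(desired)
    if a.shape != d.shape:
        raise UsageError(
            f"hamming requires equal lengths, got {a.shape} vs {d.shape}"
        )
    return int(np.count_nonzero(a != d))


def eta_of_H(H, policy: EtaPolicy):
    """Learning rate as a function of current disability H.

    fixed: eta0 for every H.  modified: eta0 below H0, then
    eta0 * sqrt(1 - ((H - H0)/(Hc - H0))^2) up to the critical disability Hc,
    and 0 beyond it.  Continuous and nonincreasing; accepts scalars or arrays.
    """
    H_arr = np.asarray(H, dtype=np.float64)
    if policy.mode == "fixed":
        out = np.full_like(H_arr, policy.eta0)
    else:
        policy.validate()
        frac = (H_arr - policy.H0) / (policy.Hc - policy.H0)
        with np.errstate(invalid="ignore"):
            mid = policy.eta0 * np.sqrt(np.clip(1.0 - frac**2, 0.0, 1.0))
        out = np.where(H_arr < policy.H0, policy.eta0, np.where(H_arr >= policy.Hc, 0.0, mid))
    return float(out) if np.isscalar(H) or H_arr.ndim == 0 else out


def hebbian_delta(s_pre, s_post, eta: float, params: ThreeLayerParams):
    """Weight change eta * (a*s_post*s_pre - b*s_post - c*s_pre).

    With the default constants this is +eta/2 when both ends are active,
    -eta/2 when exactly one is, and 0 when neither.  Works elementwise on
    arrays (use broadcasting/outer products for full matrices).
    """
    pre = np.asarray(s_pre, dtype=np.float64)
    post = np.asarray(s_post, dtype=np.float64)
    return eta * (params.a * post * pre - params.b * post - params.c * pre)


def _apply_hebbian(
    W: NDArray[np.float64],
    pre: NDArray[np.float64],
    post: NDArray[np.float64],
    update_mask: NDArray[np.bool_],
    eta: float,
    params: ThreeLayerParams,
) -> None:
    """In-place clamped Hebbian update of a weight matrix on ``update_mask``."""
    delta = eta * (
        params.a * np.outer(post, pre)
        - params.b * post[:, None]
        - params.c * pre[None, :]
    )
    W += np.where(update_mask, delta, 0.0)
    np.clip(W, params.w_min, params.w_max, out=W)


def train_step(
    state: ThreeLayerState,
    params: ThreeLayerParams,
    policy: EtaPolicy,
    rng: np.random.Generator,
) -> tuple[ThreeLayerState, int]:
    """One full time step: forward pass, disability measurement, and — while
    any output bit is wrong — a network-wide Hebbian update.

    The input->middle update uses (pre, post) = (input, actual middle
    activity); the middle->output update clamps the postsynaptic state to the
    *desired* output bit, the minimal supervised reading of learning "as long
    as a difference exists".  Connections incident to dead middle nodes are
    never updated; all weights are clipped to [w_min, w_max].  The state is
    modified in place and returned together with the step's Hamming
    disability.
    """
    m_states = middle_step(state, params, rng)
    out = output_step(state, m_states, params)
    H = hamming(out, state.desired_output)

    if H > 0:
        eta = eta_of_H(H, policy)
        if eta > 0.0:
            alive = state.alive
            m_f = m_states.astype(np.float64)
            _apply_hebbian(
                state.W_im,
                pre=state.input_pattern.astype(np.float64),
                post=m_f,
                update_mask=state.mask & alive[:, None],
                eta=eta,
                params=params,
            )
            _apply_hebbian(
                state.W_mo,
                pre=m_f,
                post=state.desired_output.astype(np.float64),
                update_mask=state.mask & alive[None, :],
                eta=eta,
                params=params,
            )
    state.t += 1
    return state, H


def pre_lesion_train(
    state: ThreeLayerState,
    params: ThreeLayerParams,
    policy: EtaPolicy,
    duration: int,
    rng: np.random.Generator,
) -> ThreeLayerState:
    """Run ``duration`` training steps (the pre-lesion learning phase;
    1000 steps in the reference experiments) and return the trained state."""
    if duration < 0:
        raise UsageError(f"duration must be >= 0, got {duration}")
    for _ in range(duration):
        train_step(state, params, policy, rng)
    return state
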