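"""Trial orchestration: full lesion trials, MAoD, grids and ordering tests.

The primary outcome throughout is the maximum amount of disability (MAoD):
the largest disability value the network endures after damage onset.  The
headline phenomenon is that MAoD decreases as the inter-removal time (IRT)
grows — slower damage of the same total size is less disabling — which these
drivers quantify over (defect size x IRT) and (package count x IRT) sweeps
with multi-seed replication and paired one-sided sign tests.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import NDArray
from scipy.stats import binomtest

from .errors import UsageError
from .homeostasis import HomeoParams, run_homeostasis_trial
from .lesion import LesionSchedule, apply_removal, removal_events
from .results import DisabilityTrace, MAoDGrid
from .threelayer import (
    EtaPolicy,
    ThreeLayerParams,
    build_network,
    eta_of_H,
    train_step,
)

__all__ = [
    "maod",
    "run_three_layer_trial",
    "average_traces",
    "paired_sign_test",
    "gradual_grid",
    "resection_grid",
    "homeostasis_irt_sweep",
    "trial_seed",
]


def maod(trace: DisabilityTrace, damage_start: int) -> float:
    """Maximum amount of disability: max of the disability series over all
    recorded times >= damage_start."""
    sel = trace.times >= damage_start
    if not sel.any():
        raise UsageError(
            f"no trace samples at or after damage_start={damage_start}"
        )
    return float(trace.disability[sel].max())


def trial_seed(master_seed: int, *indices: int) -> np.random.SeedSequence:
    """Per-trial seed derived from a master seed and cell/replicate indices,
    so grid cells are independent and individually reproducible."""
    return np.random.SeedSequence([int(master_seed), *map(int, indices)])


def default_recovery_steps(schedule: LesionSchedule) -> int:
    """Default post-lesion window: 4x the removal span plus 2000 steps, so
    the MAoD always falls inside the simulated window."""
    span = 0
    if schedule.m > 0:
        if schedule.kind == "gradual":
            span = (schedule.m - 1) * schedule.irt
        elif schedule.kind == "resection" and schedule.n_p:
            span = (schedule.n_p - 1) * schedule.irt
    return 4 * span + 2000


def run_three_layer_trial(
    params: ThreeLayerParams,
    schedule: LesionSchedule,
    policy: EtaPolicy,
    seed,
    recovery_steps: int | None = None,
) -> DisabilityTrace:
    """One complete three-layer trial: build, pre-lesion training up to the
    schedule's start_time, scheduled removals (applied before that step's
    forward pass), and a recovery phase.

    ``policy`` is the *recovery* model and takes effect at the schedule's
    start_time; the pre-lesion learning phase always runs at the fixed base
    rate eta0.  (A disability-dependent rate that vanishes beyond Hc could
    never complete the initial learning, whose starting disability is ~N/2;
    the law describes how recovery degrades with damage-induced disability.)

    Returns the full disability trace with per-step learning rate, phase
    labels and the realized removal-event log.  Identical (params, schedule,
    policy, seed) always reproduce the trace bit-exactly, and trials that
    share a seed but differ only in schedule are bit-identical before the
    first removal.
    """
    params.validate()
    policy.validate()
    schedule.validate(params.N)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = build_network(params, rng)
    schedule = schedule.resolve_start_index(rng, params.N)
    events = removal_events(schedule, params.N)
    if recovery_steps is None:
        recovery_steps = default_recovery_steps(schedule)
    last_event = events[-1][0] if events else schedule.start_time
    total_steps = last_event + recovery_steps
    first_event = events[0][0] if events else None

    by_time: dict[int, list[tuple[int, ...]]] = {}
    for t_ev, nodes in events:
        by_time.setdefault(t_ev, []).append(nodes)

    pre_policy = EtaPolicy.fixed(policy.eta0)
    H_series = np.empty(total_steps, dtype=np.float64)
    eta_series = np.empty(total_steps, dtype=np.float64)
    phase = np.empty(total_steps, dtype=object)
    for t in range(total_steps):
        for nodes in by_time.get(t, ()):
            apply_removal(state, np.asarray(nodes, dtype=np.intp))
        active = policy if t >= schedule.start_time else pre_policy
        _, H = train_step(state, params, active, rng)
        H_series[t] = H
        eta_series[t] = eta_of_H(H, active)
        if first_event is None or t < first_event:
            phase[t] = "pre"
        elif t <= last_event:
            phase[t] = "lesion"
        else:
            phase[t] = "recovery"

    return DisabilityTrace(
        times=np.arange(total_steps),
        disability=H_series,
        eta=eta_series,
        phase=phase,
        events=events,
        meta={
            "model": "three_layer",
            "time_column": "t",
            "schedule": schedule,
            "eta_mode": policy.mode,
            "n_effective": params.n_effective,
            "recovery_steps": recovery_steps,
        },
    )


def average_traces(traces: list[DisabilityTrace]) -> DisabilityTrace:
    """Pointwise mean of traces sharing a time grid and schedule (the
    many-initializations averaging used for smooth disability curves)."""
    if not traces:
        raise UsageError("average_traces requires at least one trace")
    ref = traces[0]
    for tr in traces[1:]:
        if not np.array_equal(tr.times, ref.times):
            raise UsageError("traces to average must share the same time grid")
        if tr.events != ref.events:
            raise UsageError("traces to average must share the same schedule")
    dis = np.mean([tr.disability for tr in traces], axis=0)
    eta = None
    if all(tr.eta is not None for tr in traces):
        eta = np.mean([tr.eta for tr in traces], axis=0)
    return DisabilityTrace(
        times=ref.times.copy(),
        disability=dis,
        eta=eta,
        phase=None if ref.phase is None else ref.phase.copy(),
        events=list(ref.events),
        meta={**ref.meta, "n_averaged": len(traces)},
    )


def paired_sign_test(x, y) -> float:
    """One-sided sign test that paired values x_i exceed y_i.

    Returns the p-value of #(x_i > y_i) among non-tied pairs under a fair
    coin; all-tie inputs return 1.0 (no evidence of an ordering)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise UsageError("paired_sign_test requires equal-length samples")
    wins = int(np.sum(x > y))
    losses = int(np.sum(x < y))
    n_eff = wins + losses
    if n_eff == 0:
        return 1.0
    return float(binomtest(wins, n_eff, 0.5, alternative="greater").pvalue)


def _schedule_variant(base: LesionSchedule, **kw) -> LesionSchedule:
    fields = dict(
        kind=base.kind,
        m=base.m,
        irt=base.irt,
        n_p=base.n_p,
        start_time=base.start_time,
        start_index=base.start_index,
    )
    fields.update(kw)
    return LesionSchedule(**fields)


def gradual_grid(
    params: ThreeLayerParams,
    policy: EtaPolicy,
    m_values,
    irt_values,
    n_seeds: int,
    master_seed: int = 0,
    start_time: int = 1000,
    start_index: int | None = None,
    recovery_steps: int | None = None,
) -> MAoDGrid:
    """MAoD over a (defect size x IRT) sweep of gradual injuries.

    Per-cell replicate seeds derive from (master_seed, i, j, replicate), so
    cells are independent of axis enumeration order and individually
    reproducible."""
    m_values = list(m_values)
    irt_values = list(irt_values)
    if not m_values or not irt_values or n_seeds < 1:
        raise UsageError("gradual_grid requires nonempty axes and n_seeds >= 1")
    values = np.empty((len(m_values), len(irt_values), n_seeds))
    for i, m in enumerate(m_values):
        for j, irt in enumerate(irt_values):
            sched = LesionSchedule(
                kind="gradual", m=int(m), irt=int(irt),
                start_time=start_time, start_index=start_index,
            )
            for r in range(n_seeds):
                trace = run_three_layer_trial(
                    params, sched, policy,
                    seed=np.random.default_rng(trial_seed(master_seed, i, j, r)),
                    recovery_steps=recovery_steps,
                )
                values[i, j, r] = maod(trace, start_time)
    return MAoDGrid(
        axis1_name="m", axis1=np.asarray(m_values),
        axis2_name="irt", axis2=np.asarray(irt_values),
        values=values,
        meta={"master_seed": master_seed, "eta_mode": policy.mode,
              "N": params.N, "n": params.n, "kind": "gradual"},
    )


def resection_grid(
    params: ThreeLayerParams,
    policy: EtaPolicy,
    m: int,
    np_values,
    irt_values,
    n_seeds: int,
    master_seed: int = 0,
    start_time: int = 1000,
    start_index: int | None = None,
    recovery_steps: int | None = None,
) -> MAoDGrid:
    """MAoD over a (package count x IRT) sweep of resection injuries with
    fixed total defect size m."""
    np_values = list(np_values)
    irt_values = list(irt_values)
    if not np_values or not irt_values or n_seeds < 1:
        raise UsageError("resection_grid requires nonempty axes and n_seeds >= 1")
    if any(v > m for v in np_values):
        raise UsageError(f"package counts must not exceed m={m}")
    values = np.empty((len(np_values), len(irt_values), n_seeds))
    for i, n_p in enumerate(np_values):
        for j, irt in enumerate(irt_values):
            sched = LesionSchedule(
                kind="resection", m=int(m), irt=int(irt), n_p=int(n_p),
                start_time=start_time, start_index=start_index,
            )
            for r in range(n_seeds):
                trace = run_three_layer_trial(
                    params, sched, policy,
                    seed=np.random.default_rng(trial_seed(master_seed, i, j, r)),
                    recovery_steps=recovery_steps,
                )
                values[i, j, r] = maod(trace, start_time)
    return MAoDGrid(
        axis1_name="n_p", axis1=np.asarray(np_values),
        axis2_name="irt", axis2=np.asarray(irt_values),
        values=values,
        meta={"master_seed": master_seed, "eta_mode": policy.mode,
              "N": params.N, "n": params.n, "kind": "resection", "m": m},
    )


def homeostasis_irt_sweep(
    params: HomeoParams,
    m: int,
    irt_values,
    n_seeds: int,
    master_seed: int = 0,
    start_time: int = 2700,
    start_index: int | None = None,
    total_morph_steps: int | None = None,
) -> MAoDGrid:
    """Per-IRT mean peak post-lesion disability of the homeostasis model
    (a 1 x k MAoD grid over gradual removal of m contiguous neurons)."""
    irt_values = list(irt_values)
    if not irt_values or n_seeds < 1:
        raise UsageError("homeostasis_irt_sweep requires nonempty irt_values and n_seeds >= 1")
    values = np.empty((1, len(irt_values), n_seeds))
    for j, irt in enumerate(irt_values):
        sched = LesionSchedule(
            kind="gradual", m=int(m), irt=int(irt),
            start_time=start_time, start_index=start_index,
        )
        span = (m - 1) * int(irt) if m > 0 else 0
        total = total_morph_steps
        if total is None:
            total = start_time + span + 200
        for r in range(n_seeds):
            trace = run_homeostasis_trial(
                params, sched, total,
                seed=np.random.default_rng(trial_seed(master_seed, 0, j, r)),
            )
            values[0, j, r] = maod(trace, start_time)
    return MAoDGrid(
        axis1_name="m", axis1=np.asarray([m]),
        axis2_name="irt", axis2=np.asarray(irt_values),
        values=values,
        meta={"master_seed": master_seed, "model": "homeostasis",
              "n_nodes": params.n_nodes, "start_time": start_time},
    )
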