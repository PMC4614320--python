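"""Declarative lesion schedules and their application.

Three spatio-temporal injury types, all removing a contiguous modular block
of ``m`` nodes starting at ``start_index``:

* ``immediate`` — all m nodes at once at ``start_time``;
* ``gradual``   — one node every ``irt`` time units, in ring order;
* ``resection`` — ``n_p`` packages of ~m/n_p contiguous nodes, one package
  every ``irt`` time units.

Immediate injury is exactly gradual or resection with irt=0.  Time units are
simulation steps for the three-layer model and morphological steps for the
homeostasis model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = ["LesionSchedule", "removal_events", "apply_removal"]

_KINDS = ("immediate", "gradual", "resection")


@dataclass(frozen=True)
class LesionSchedule:
    """When which nodes die.  ``start_index=None`` means "draw once from the
    run seed" (resolved and logged by the experiment driver)."""

    kind: str = "immediate"
    m: int = 0
    irt: int = 0
    n_p: int | None = None
    start_time: int = 1000
    start_index: int | None = 0

    def validate(self, n_nodes: int) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(
                f"lesion kind must be one of {_KINDS}, got {self.kind!r}"
            )
        if not 0 <= self.m <= n_nodes:
            raise ConfigurationError(
                f"defect size m must satisfy 0 <= m <= N, got m={self.m}, N={n_nodes}"
            )
        if self.irt < 0:
            raise ConfigurationError(f"irt must be >= 0, got irt={self.irt}")
        if self.start_time < 0:
            raise ConfigurationError(
                f"start_time must be >= 0, got start_time={self.start_time}"
            )
        if self.kind == "resection" and self.m > 0:
            if self.n_p is None or not 1 <= self.n_p <= self.m:
                raise ConfigurationError(
                    f"resection requires 1 <= n_p <= m, got n_p={self.n_p}, m={self.m}"
                )

    def resolve_start_index(self, rng: np.random.Generator, n_nodes: int) -> "LesionSchedule":
        """Return a schedule with a concrete start_index, drawing it from
        ``rng`` if unset.  Always consumes one draw so random streams stay
        aligned across schedule variants sharing a seed."""
        drawn = int(rng.integers(n_nodes))
        if self.start_index is not None:
            return self
        return LesionSchedule(
            kind=self.kind,
            m=self.m,
            irt=self.irt,
            n_p=self.n_p,
            start_time=self.start_time,
            start_index=drawn,
        )


def removal_events(
    schedule: LesionSchedule, n_nodes: int
) -> list[tuple[int, tuple[int, ...]]]:
    """Expand a schedule into an ordered list of (time, node-index tuple).

    Gradual removal proceeds in ring order from ``start_index``.  For
    resection with ``m`` not divisible by ``n_p``, the earliest packages take
    one extra node each, keeping packages as equal as possible.  The event
    node sets are disjoint and their union has exactly ``m`` nodes.
    """
    schedule.validate(n_nodes)
    if schedule.m == 0:
        return []
    if schedule.start_index is None:
        raise ConfigurationError(
            "start_index is unset; call resolve_start_index before expanding "
            "removal_events"
        )
    block = [(schedule.start_index + k) % n_nodes for k in range(schedule.m)]
    t0 = schedule.start_time

    if schedule.kind == "immediate":
        return [(t0, tuple(block))]
    if schedule.kind == "gradual":
        return [(t0 + k * schedule.irt, (node,)) for k, node in enumerate(block)]
    # resection
    n_p = schedule.n_p
    base, rem = divmod(schedule.m, n_p)
    sizes = [base + 1] * rem + [base] * (n_p - rem)
    events = []
    pos = 0
    for k, size in enumerate(sizes):
        events.append((t0 + k * schedule.irt, tuple(block[pos : pos + size])))
        pos += size
    return events


def apply_removal(state, nodes) -> None:
    """Kill the given nodes in either model's state (in place).

    Delegates to the state's ``kill`` method: the three-layer model clears
    alive flags and zeroes incident weights; the homeostasis model deletes
    all in/out synapses and bars the neuron from future synapse formation.
    Removing an already-dead node is a no-op with a logged warning.
    """
    nodes = np.atleast_1d(np.asarray(nodes, dtype=np.intp))
    already_dead = nodes[~state.alive[nodes]]
    if already_dead.size:
        logger.warning(
            "apply_removal: nodes %s are already dead; no-op for them",
            already_dead.tolist(),
        )
    state.kill(nodes)
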