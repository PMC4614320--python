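"""Result containers: per-step disability traces and MAoD sweep grids."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .errors import UsageError

__all__ = ["DisabilityTrace", "MAoDGrid"]


@dataclass
class DisabilityTrace:
    """Per-time-step disability series from one trial (or an average of
    trials sharing a schedule).

    ``disability`` is the Hamming distance for the three-layer model and the
    across-neuron variance of time-averaged firing probability for the
    homeostasis model.  ``eta`` is the per-step learning rate (three-layer
    only).  ``extras`` holds model-specific columns (e.g. alive_count,
    mean_F, total_synapses).  ``events`` is the realized removal log as
    (time, node tuple) pairs.
    """

    times: NDArray[np.int64]
    disability: NDArray[np.float64]
    eta: NDArray[np.float64] | None = None
    phase: NDArray | None = None
    events: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        self.disability = np.asarray(self.disability, dtype=np.float64)
        if self.times.shape != self.disability.shape:
            raise UsageError("times and disability must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise UsageError("trace times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def nodes_removed_cum(self) -> NDArray[np.int64]:
        """Cumulative number of removed nodes at each recorded time."""
        out = np.zeros(len(self.times), dtype=np.int64)
        for t_ev, nodes in self.events:
            out += np.where(self.times >= t_ev, len(nodes), 0)
        return out

    def to_frame(self) -> pd.DataFrame:
        time_col = self.meta.get("time_column", "t")
        data = {time_col: self.times, "disability": self.disability}
        if self.eta is not None:
            data["eta"] = self.eta
        data["nodes_removed_cum"] = self.nodes_removed_cum
        if self.phase is not None:
            data["phase"] = self.phase
        for name, col in self.extras.items():
            data[name] = col
        return pd.DataFrame(data)


@dataclass
class MAoDGrid:
    """Maximum-amount-of-disability surface over a (size-or-packages x IRT)
    sweep with multi-seed replication.

    ``values`` has shape (len(axis1), len(axis2), n_seeds); per-cell means
    are always recomputed from the stored per-seed values.
    """

    axis1_name: str
    axis1: NDArray
    axis2_name: str
    axis2: NDArray
    values: NDArray[np.float64]
    seeds: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis1 = np.asarray(self.axis1)
        self.axis2 = np.asarray(self.axis2)
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (len(self.axis1), len(self.axis2))
        if self.values.shape[:2] != expected:
            raise UsageError(
                f"values shape {self.values.shape} does not match axes {expected}"
            )

    @property
    def n_seeds(self) -> int:
        return self.values.shape[2]

    @property
    def means(self) -> NDArray[np.float64]:
        return self.values.mean(axis=2)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (axis1, axis2, seed replicate)."""
        rows = []
        for i, a1 in enumerate(self.axis1):
            for j, a2 in enumerate(self.axis2):
                for r in range(self.n_seeds):
                    rows.append((a1, a2, r, self.values[i, j, r]))
        return pd.DataFrame(
            rows, columns=[self.axis1_name, self.axis2_name, "replicate", "maod"]
        )

    def summary_frame(self) -> pd.DataFrame:
        """Per-cell mean table."""
        rows = []
        means = self.means
        for i, a1 in enumerate(self.axis1):
            for j, a2 in enumerate(self.axis2):
                rows.append((a1, a2, means[i, j]))
        return pd.DataFrame(
            rows, columns=[self.axis1_name, self.axis2_name, "mean_maod"]
        )
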