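"""Spike event records shared by the stimulus generator and the simulator."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpikeRecord"]


@dataclass
class SpikeRecord:
    """An event list of (neuron id, spike time in ms).

    ``label`` identifies the channel or population the events belong to
    (e.g. ``"stimulus"``, ``"noise_exc"``, ``"noise_inh"``, ``"E"``, ``"I"``).
    Events are kept sorted by time (ties by neuron id).
    """

    neuron_ids: np.ndarray
    times: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if self.neuron_ids.shape != self.times.shape:
            raise ValueError("neuron_ids and times must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) < 0):
            order = np.lexsort((self.neuron_ids, self.times))
            self.neuron_ids = self.neuron_ids[order]
            self.times = self.times[order]

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def empty(cls, label: str = "") -> "SpikeRecord":
        return cls(np.empty(0, dtype=np.int64), np.empty(0), label=label)

    def counts(self, n_neurons: int, t_start: float | None = None,
               t_end: float | None = None) -> np.ndarray:
        """Per-neuron spike counts, optionally restricted to [t_start, t_end)."""
        ids = self.neuron_ids
        if t_start is not None or t_end is not None:
            lo = -np.inf if t_start is None else t_start
            hi = np.inf if t_end is None else t_end
            ids = ids[(self.times >= lo) & (self.times < hi)]
        return np.bincount(ids, minlength=n_neurons)

    def mean_rate(self, n_neurons: int, t_start: float, t_end: float) -> float:
        """Population-average firing rate (Hz) over the window [t_start, t_end)."""
        if t_end <= t_start:
            raise ValueError("empty window")
        total = np.count_nonzero((self.times >= t_start) & (self.times < t_end))
        return total / n_neurons / ((t_end - t_start) / 1000.0)

    def select(self, neuron_mask: np.ndarray) -> "SpikeRecord":
        keep = neuron_mask[self.neuron_ids]
        return SpikeRecord(self.neuron_ids[keep], self.times[keep], self.label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"neuron_id": self.neuron_ids,
                             "time_ms": self.times,
                             "channel": self.label})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpikeRecord":
        df = pd.read_csv(path)
        label = str(df["channel"].iloc[0]) if len(df) else ""
        return cls(df["neuron_id"].to_numpy(), df["time_ms"].to_numpy(), label)
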