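"""Spike-raster container shared by the simulator, fixtures and measures."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["SpikeRaster"]


@dataclass(frozen=True)
class SpikeRaster:
    """Ordered (neuron_id, spike_time) pairs over ``n_neurons`` cells.

    Times are in ms, globally sorted (hence strictly increasing per
    neuron up to coincidences at the integration-step resolution).
    """

    neuron_ids: np.ndarray
    times: np.ndarray
    n_neurons: int

    def __post_init__(self) -> None:
        ids = np.asarray(self.neuron_ids, dtype=np.int64)
        t = np.asarray(self.times, dtype=np.float64)
        if ids.shape != t.shape or ids.ndim != 1:
            raise ValueError("neuron_ids and times must be matching 1-D arrays")
        if ids.size and (ids.min() < 0 or ids.max() >= self.n_neurons):
            raise ValueError("neuron id out of range")
        object.__setattr__(self, "neuron_ids", ids)
        object.__setattr__(self, "times", t)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def sorted_by_time(self) -> "SpikeRaster":
        order = np.argsort(self.times, kind="stable")
        return SpikeRaster(self.neuron_ids[order], self.times[order], self.n_neurons)

    def in_window(self, t_start: float, t_end: float) -> "SpikeRaster":
        m = (self.times >= t_start) & (self.times < t_end)
        return SpikeRaster(self.neuron_ids[m], self.times[m], self.n_neurons)

    def spike_trains(self) -> list[np.ndarray]:
        """Per-neuron sorted spike-time arrays."""
        trains: list[np.ndarray] = []
        for i in range(self.n_neurons):
            t = self.times[self.neuron_ids == i]
            trains.append(np.sort(t))
        return trains

    def relabeled(self, permutation: np.ndarray) -> "SpikeRaster":
        """Apply a permutation to the neuron labels (new_id = perm[old_id])."""
        perm = np.asarray(permutation, dtype=np.int64)
        if perm.size != self.n_neurons:
            raise ValueError("permutation length must equal n_neurons")
        return SpikeRaster(perm[self.neuron_ids], self.times, self.n_neurons)

    @staticmethod
    def from_trains(trains: list[np.ndarray], n_neurons: Optional[int] = None) -> "SpikeRaster":
        n = len(trains) if n_neurons is None else n_neurons
        ids = np.concatenate([np.full(len(t), i, dtype=np.int64) for i, t in enumerate(trains)]) \
            if trains else np.empty(0, dtype=np.int64)
        times = np.concatenate([np.asarray(t, dtype=float) for t in trains]) \
            if trains else np.empty(0, dtype=float)
        return SpikeRaster(ids, times, n).sorted_by_time()
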