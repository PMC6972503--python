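"""Synthetic spike rasters with controlled coherence.

These generators emulate the dynamical regimes a simulated inhibitory
network can occupy -- perfect population synchrony, jittered synchrony,
independent Poisson firing, phase-shifted cluster states, and silence --
so that every analysis statistic can be exercised and validated without
running the simulator.  They test the measures, not the dynamics: a
fixture is never a surrogate for a simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .measures import MeasureWindow
from .raster import SpikeRaster

__all__ = ["FixtureSpec", "make_raster", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("synchronous", "jittered", "poisson", "clustered", "silent")


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of one synthetic raster.

    ``kind`` selects the regime; ``rate`` is the per-cell firing rate in
    Hz; ``jitter_sd`` (ms) applies to the jittered kind; ``n_clusters``
    to the clustered kind.  All randomness is reproducible under ``seed``.
    """

    kind: str
    N: int
    window: MeasureWindow
    rate: float = 30.0
    jitter_sd: float = 0.0
    n_clusters: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {FIXTURE_KINDS}")
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be at least 1")
        if self.N < 1:
            raise ValueError("N must be at least 1")


def _periodic_train(window: MeasureWindow, rate: float, phase: float = 0.0) -> np.ndarray:
    if rate <= 0:
        return np.empty(0)
    period = 1000.0 / rate
    first = window.t_start + phase
    times = np.arange(first, window.t_end, period)
    return times[times >= window.t_start]


def make_raster(spec: FixtureSpec) -> SpikeRaster:
    """Generate the raster described by ``spec``.

    - synchronous: one shared periodic train copied to every cell.
    - jittered: the synchronous raster plus i.i.d. Gaussian time jitter
      of SD ``jitter_sd``; jitter that leaves the window is clipped to
      the window edge (spike counts are preserved).
    - poisson: independent homogeneous Poisson trains at ``rate``.
    - clustered: ``n_clusters`` cell groups firing the shared periodic
      train at phases spaced uniformly over one period.
    - silent: no spikes.
    """
    rng = np.random.default_rng(spec.seed)
    w = spec.window

    if spec.kind == "silent":
        return SpikeRaster(np.empty(0, np.int64), np.empty(0), spec.N)

    if spec.kind == "synchronous":
        base = _periodic_train(w, spec.rate)
        trains = [base.copy() for _ in range(spec.N)]
        return SpikeRaster.from_trains(trains, spec.N)

    if spec.kind == "jittered":
        base = _periodic_train(w, spec.rate)
        trains = []
        eps = 1e-9
        for _ in range(spec.N):
            t = base + rng.normal(0.0, spec.jitter_sd, size=base.size) \
                if spec.jitter_sd > 0 else base.copy()
            t = np.clip(t, w.t_start, w.t_end - eps)
            trains.append(np.sort(t))
        return SpikeRaster.from_trains(trains, spec.N)

    if spec.kind == "poisson":
        trains = []
        for _ in range(spec.N):
            if spec.rate <= 0:
                trains.append(np.empty(0))
                continue
            n = rng.poisson(spec.rate * w.length / 1000.0)
            trains.append(np.sort(rng.uniform(w.t_start, w.t_end, size=n)))
        return SpikeRaster.from_trains(trains, spec.N)

    # clustered
    period = 1000.0 / spec.rate if spec.rate > 0 else w.length
    phases = [k * period / spec.n_clusters for k in range(spec.n_clusters)]
    trains = []
    for i in range(spec.N):
        cluster = i % spec.n_clusters
        trains.append(_periodic_train(w, spec.rate, phase=phases[cluster]))
    return SpikeRaster.from_trains(trains, spec.N)
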