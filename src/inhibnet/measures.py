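"""Synchrony, bistability, firing-rate and transition-sharpness statistics.

The synchrony measure follows Golomb & Rinzel: each cell's spike train
is convolved with a Gaussian kernel to give a smooth trace V_i(t); with
population mean trace V(t) = (1/N) sum_i V_i(t), the measure is

    S = Var_t[V(t)] / ( (1/N) sum_i Var_t[V_i(t)] )

with variances time-averaged over the analysis window.  S = 0 marks
completely asynchronous firing and S = 1 a fully synchronous population
(identical traces).  Cells with zero trace variance in the window
(silent cells) are excluded from the denominator mean -- including them
would push S toward divergence -- and their count is reported.  If the
window is silent, or every individual variance vanishes, the measure is
undefined and returned as NaN, never silently 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .raster import SpikeRaster

__all__ = [
    "MeasureWindow",
    "PRE_WINDOW",
    "POST_WINDOW",
    "DEFAULT_KERNEL_SD",
    "DEFAULT_GRID_STEP",
    "SYNCHRONY_CUTOFF",
    "BISTABILITY_THRESHOLD",
    "ConvolvedTraces",
    "smoothed_traces",
    "synchrony_measure",
    "synchrony_details",
    "delta_synchrony",
    "bistability_measure",
    "mean_firing_frequency",
    "classify_synchrony",
    "transition_slope",
]

DEFAULT_KERNEL_SD = 2.0    # ms; on the order of the synaptic rise time
DEFAULT_GRID_STEP = 0.5    # ms
KERNEL_TRUNC_SD = 5.0      # kernel support is +- 5 SD
SYNCHRONY_CUTOFF = 0.25    # S above this classifies as synchronous
BISTABILITY_THRESHOLD = 0.3


@dataclass(frozen=True)
class MeasureWindow:
    """Half-open analysis window [t_start, t_end) in ms."""

    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def length(self) -> float:
        return self.t_end - self.t_start


PRE_WINDOW = MeasureWindow(500.0, 1000.0)    # random-initial-conditions window
POST_WINDOW = MeasureWindow(1500.0, 2000.0)  # following-perturbation window


@dataclass(frozen=True)
class ConvolvedTraces:
    """Gaussian-smoothed spike-density traces on a uniform grid."""

    traces: np.ndarray       # (N, n_grid)
    grid: np.ndarray         # (n_grid,)
    kernel_sd: float
    grid_step: float

    @property
    def population_mean(self) -> np.ndarray:
        return self.traces.mean(axis=0)


def smoothed_traces(
    raster: SpikeRaster,
    window: MeasureWindow,
    kernel_sd: float = DEFAULT_KERNEL_SD,
    grid_step: float = DEFAULT_GRID_STEP,
    N: Optional[int] = None,
) -> ConvolvedTraces:
    """Convolve each cell's spike train with a Gaussian kernel.

    The kernel (SD ``kernel_sd`` ms, truncated at +-5 SD) is evaluated
    exactly at each grid point from each spike time -- no pre-binning --
    so sub-grid spike timing is preserved.  Only spikes inside the
    half-open window [t_start, t_end) contribute: activity beyond the
    window edge (e.g. the perturbation response just after the
    pre-perturbation window closes) must not leak into the measure
    through kernel tails.
    """
    if kernel_sd <= 0 or grid_step <= 0:
        raise ValueError("kernel_sd and grid_step must be positive")
    N = raster.n_neurons if N is None else N
    n_grid = int(round(window.length / grid_step)) + 1
    grid = window.t_start + grid_step * np.arange(n_grid)

    reach = KERNEL_TRUNC_SD * kernel_sd
    m = (raster.times >= window.t_start) & (raster.times < window.t_end)
    ids = raster.neuron_ids[m]
    times = raster.times[m]

    traces = np.zeros((N, n_grid))
    if times.size:
        half = int(math.ceil(reach / grid_step))
        offsets = np.arange(-half, half + 1)
        # nearest grid index to each spike, then evaluate the kernel on the
        # surrounding +-half columns exactly
        centre = np.round((times - window.t_start) / grid_step).astype(np.int64)
        cols = centre[:, None] + offsets[None, :]          # (n_spikes, 2*half+1)
        valid = (cols >= 0) & (cols < n_grid)
        tgrid = window.t_start + cols * grid_step
        vals = np.exp(-0.5 * ((tgrid - times[:, None]) / kernel_sd) ** 2)
        vals[(np.abs(tgrid - times[:, None]) > reach) | ~valid] = 0.0
        flat = ids[:, None] * n_grid + np.clip(cols, 0, n_grid - 1)
        traces = np.bincount(
            flat.ravel(), weights=vals.ravel(), minlength=N * n_grid
        ).reshape(N, n_grid)
    return ConvolvedTraces(traces=traces, grid=grid, kernel_sd=kernel_sd, grid_step=grid_step)


class SynchronyDetails(NamedTuple):
    S: float
    n_active: int
    n_excluded_silent: int


def synchrony_details(
    raster: SpikeRaster,
    window: MeasureWindow,
    kernel_sd: float = DEFAULT_KERNEL_SD,
    grid_step: float = DEFAULT_GRID_STEP,
    N: Optional[int] = None,
) -> SynchronyDetails:
    """Synchrony measure plus active/excluded cell counts."""
    ct = smoothed_traces(raster, window, kernel_sd, grid_step, N)
    var_i = ct.traces.var(axis=1)  # time-averaged per-cell variance
    active = var_i > 0
    n_active = int(active.sum())
    n_total = ct.traces.shape[0]
    if n_active == 0:
        return SynchronyDetails(float("nan"), 0, n_total)
    var_pop = float(ct.population_mean.var())
    S = var_pop / float(var_i[active].mean())
    return SynchronyDetails(S, n_active, n_total - n_active)


def synchrony_measure(
    raster: SpikeRaster,
    window: MeasureWindow,
    kernel_sd: float = DEFAULT_KERNEL_SD,
    grid_step: float = DEFAULT_GRID_STEP,
    N: Optional[int] = None,
) -> float:
    """Golomb-Rinzel synchrony measure S in [0, 1] (NaN if undefined)."""
    return synchrony_details(raster, window, kernel_sd, grid_step, N).S


class DeltaSynchrony(NamedTuple):
    S_before: float
    S_after: float
    diff: float


def delta_synchrony(
    raster: SpikeRaster,
    pre: MeasureWindow = PRE_WINDOW,
    post: MeasureWindow = POST_WINDOW,
    kernel_sd: float = DEFAULT_KERNEL_SD,
    grid_step: float = DEFAULT_GRID_STEP,
) -> DeltaSynchrony:
    """S before and after the perturbation, and their difference.

    ``diff = S_after - S_before``; NaN propagates from either window, so a
    silent window flags the comparison as undefined rather than inventing
    a zero.
    """
    s_before = synchrony_measure(raster, pre, kernel_sd, grid_step)
    s_after = synchrony_measure(raster, post, kernel_sd, grid_step)
    return DeltaSynchrony(s_before, s_after, s_after - s_before)


def bistability_measure(
    diff_map: np.ndarray,
    threshold: float = BISTABILITY_THRESHOLD,
    return_excluded: bool = False,
):
    """Sum of synchrony-difference entries strictly exceeding ``threshold``.

    The entries themselves are summed (not indicator counts), so larger
    transitions weigh more.  Undefined (NaN) entries are skipped; their
    count is available via ``return_excluded=True``.
    """
    diffs = np.asarray(diff_map, dtype=float).ravel()
    defined = ~np.isnan(diffs)
    score = float(diffs[defined & (diffs > threshold)].sum())
    if return_excluded:
        return score, int((~defined).sum())
    return score


def mean_firing_frequency(
    raster: SpikeRaster,
    window: MeasureWindow,
    N: Optional[int] = None,
) -> float:
    """Population mean firing rate over the window, in Hz.

    Total spikes in the window, divided by the cell count and by the
    window length (converted from ms to s).  A silent window gives 0 Hz.
    """
    N = raster.n_neurons if N is None else N
    n_spikes = raster.in_window(window.t_start, window.t_end).n_spikes
    return 1000.0 * n_spikes / (N * window.length)


def classify_synchrony(S: float, cutoff: float = SYNCHRONY_CUTOFF) -> str:
    """Label a synchrony value: 'synchronous' iff S > cutoff (strict)."""
    if math.isnan(S):
        raise ValueError("cannot classify an undefined synchrony measure")
    return "synchronous" if S > cutoff else "asynchronous"


def transition_slope(
    S_vs_I: Sequence[tuple[float, float]],
    S_max_panel: float,
) -> float:
    """Sharpness of the asynchrony-to-synchrony transition along a drive sweep.

    Given (I_mu, S) pairs sorted by ascending I_mu, locate the first index
    k whose S exceeds half the panel-wide maximum ``S_max_panel``; the
    slope is (S_k - S_{k-1}) / (I_k - I_{k-1}) in 1/pA.  Returns NaN if no
    point exceeds half-max or if the first point already does (no earlier
    point to anchor the segment).
    """
    pairs = list(S_vs_I)
    if len(pairs) < 2:
        return float("nan")
    I = np.array([p[0] for p in pairs], dtype=float)
    S = np.array([p[1] for p in pairs], dtype=float)
    if np.any(np.diff(I) <= 0):
        raise ValueError("I values must be strictly increasing")
    half = S_max_panel / 2.0
    above = np.where(S > half)[0]
    if above.size == 0 or above[0] == 0:
        return float("nan")
    k = int(above[0])
    return float((S[k] - S[k - 1]) / (I[k] - I[k - 1]))
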