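"""Parameter-sweep orchestration over (g_syn x I_mu) grids.

Each grid cell runs ``n_seeds`` independent simulations (fresh topology,
drive and initial conditions, derived deterministically from a master
seed) and stores seed-averaged synchrony before/after the perturbation,
their difference, and the mean firing frequency, alongside every
per-seed value for audit.  Cells are mutually independent, so any
execution order yields identical results.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import SimulationBlowupError, StimulusProtocol, simulate
from .measures import (
    BISTABILITY_THRESHOLD,
    PRE_WINDOW,
    SYNCHRONY_CUTOFF,
    MeasureWindow,
    bistability_measure,
    delta_synchrony,
    mean_firing_frequency,
    transition_slope,
)
from .model import IzhikevichParams, make_preset
from .network import NetworkConfig

__all__ = [
    "SweepSpec",
    "HeatmapGrid",
    "derive_seeds",
    "run_sweep",
    "compare_panels",
    "slope_table",
    "synchrony_border",
]


@dataclass(frozen=True)
class SweepSpec:
    """One heatmap panel: a preset swept over (g_syn x I_mu)."""

    preset: str
    g_syn_values: tuple[float, ...]
    I_mu_values: tuple[float, ...]
    p_conn: float = 0.12
    sigma_I: float = 6.0
    N: int = 500
    n_seeds: int = 5
    master_seed: int = 0
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)

    def __post_init__(self) -> None:
        g = np.asarray(self.g_syn_values, float)
        I = np.asarray(self.I_mu_values, float)
        if g.size == 0 or I.size == 0:
            raise ValueError("grid axes must be non-empty")
        if np.any(np.diff(g) <= 0) or np.any(np.diff(I) <= 0):
            raise ValueError("grid axes must be strictly increasing")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be at least 1")
        make_preset(self.preset)  # validates the name
        object.__setattr__(self, "g_syn_values", tuple(float(x) for x in g))
        object.__setattr__(self, "I_mu_values", tuple(float(x) for x in I))


@dataclass(frozen=True)
class HeatmapGrid:
    """Seed-averaged maps over (g_syn x I_mu) with full per-seed audit trail.

    Matrices are indexed [g_index, I_index]; the ``*_seeds`` arrays carry
    one extra trailing axis of length ``n_seeds``.
    """

    g_syn_values: tuple[float, ...]
    I_mu_values: tuple[float, ...]
    S_before: np.ndarray
    S_after: np.ndarray
    diff: np.ndarray
    mean_firing_frequency: np.ndarray
    S_before_seeds: np.ndarray
    S_after_seeds: np.ndarray
    meta: dict

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.g_syn_values), len(self.I_mu_values))

    def same_axes(self, other: "HeatmapGrid") -> bool:
        return (self.g_syn_values == other.g_syn_values
                and self.I_mu_values == other.I_mu_values)


def derive_seeds(master_seed: int, g_index: int, I_index: int, replicate: int) -> tuple[int, int, int]:
    """Independent (topology, drive, init) seeds for one cell replicate.

    Counter-based derivation from (master, cell, replicate) keeps grids
    embarrassingly parallel yet fully deterministic.
    """
    ss = np.random.SeedSequence(entropy=(master_seed, g_index, I_index, replicate))
    children = ss.spawn(3)
    return tuple(int(c.generate_state(1)[0]) for c in children)


def run_sweep(spec: SweepSpec, progress: bool = False) -> HeatmapGrid:
    """Run every cell of the sweep and assemble the heatmap grid.

    A replicate whose simulation blows up, or whose synchrony measure is
    undefined (silent window), contributes NaN; seed averages use the
    remaining replicates, and a cell with no valid replicate is NaN.
    """
    params = make_preset(spec.preset)
    nG, nI = len(spec.g_syn_values), len(spec.I_mu_values)
    Sb = np.full((nG, nI, spec.n_seeds), np.nan)
    Sa = np.full((nG, nI, spec.n_seeds), np.nan)
    mff = np.full((nG, nI, spec.n_seeds), np.nan)

    for gi, g_syn in enumerate(spec.g_syn_values):
        for ii, I_mu in enumerate(spec.I_mu_values):
            for rep in range(spec.n_seeds):
                s_top, s_drv, s_ini = derive_seeds(spec.master_seed, gi, ii, rep)
                cfg = NetworkConfig(
                    N=spec.N, p_conn=spec.p_conn, g_syn=g_syn,
                    I_mu=I_mu, sigma_I=spec.sigma_I,
                    seed_topology=s_top, seed_drive=s_drv, seed_init=s_ini,
                )
                try:
                    res = simulate(cfg, params, proto=spec.protocol)
                except SimulationBlowupError:
                    continue
                ds = delta_synchrony(res.raster)
                Sb[gi, ii, rep] = ds.S_before
                Sa[gi, ii, rep] = ds.S_after
                mff[gi, ii, rep] = mean_firing_frequency(res.raster, PRE_WINDOW)
            if progress:
                print(f"[sweep {spec.preset}] g_syn={g_syn} I_mu={I_mu} done", flush=True)

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        S_before = np.nanmean(Sb, axis=2)
        S_after = np.nanmean(Sa, axis=2)
        mff_mean = np.nanmean(mff, axis=2)
    diff = S_after - S_before
    meta = {
        "preset": spec.preset,
        "p_conn": spec.p_conn,
        "sigma_I": spec.sigma_I,
        "N": spec.N,
        "n_seeds": spec.n_seeds,
        "master_seed": spec.master_seed,
        "protocol": dataclasses.asdict(spec.protocol),
    }
    return HeatmapGrid(
        g_syn_values=spec.g_syn_values,
        I_mu_values=spec.I_mu_values,
        S_before=S_before, S_after=S_after, diff=diff,
        mean_firing_frequency=mff_mean,
        S_before_seeds=Sb, S_after_seeds=Sa,
        meta=meta,
    )


def compare_panels(
    grid_control: HeatmapGrid,
    grid_4ap: HeatmapGrid,
    threshold: float = BISTABILITY_THRESHOLD,
) -> tuple[float, float]:
    """Bistability measure of two panels computed over identical axes."""
    if not grid_control.same_axes(grid_4ap):
        raise ValueError("panels must share identical (g_syn, I_mu) axes")
    return (
        bistability_measure(grid_control.diff, threshold),
        bistability_measure(grid_4ap.diff, threshold),
    )


def slope_table(
    panel_pairs: Sequence[tuple[HeatmapGrid, HeatmapGrid]],
    g_syn_slices: Sequence[float],
) -> pd.DataFrame:
    """Transition-sharpness slopes for matched control / 4-AP panels.

    For each condition pair and each requested g_syn slice, the
    random-initial-conditions synchrony column S(I_mu) is reduced to its
    transition slope, using that panel's grid-wide maximum as the
    half-max reference.  Rows: (p_conn, sigma_I, g_syn, control_slope,
    fourap_slope); undefined slopes are NaN.
    """
    rows = []
    for grid_c, grid_f in panel_pairs:
        if not grid_c.same_axes(grid_f):
            raise ValueError("panel pair must share identical axes")
        for g in g_syn_slices:
            row: dict = {
                "p_conn": grid_c.meta.get("p_conn"),
                "sigma_I": grid_c.meta.get("sigma_I"),
                "g_syn": g,
            }
            for label, grid in (("control_slope", grid_c), ("fourap_slope", grid_f)):
                gi = int(np.argmin(np.abs(np.asarray(grid.g_syn_values) - g)))
                if not np.isclose(grid.g_syn_values[gi], g):
                    raise ValueError(f"g_syn slice {g} not on the grid axis")
                col = grid.S_before[gi, :]
                panel_max = float(np.nanmax(grid.S_before))
                pairs = [
                    (I, S) for I, S in zip(grid.I_mu_values, col) if not np.isnan(S)
                ]
                row[label] = transition_slope(pairs, panel_max) if len(pairs) >= 2 else float("nan")
            rows.append(row)
    return pd.DataFrame(rows, columns=["p_conn", "sigma_I", "g_syn", "control_slope", "fourap_slope"])


def synchrony_border(
    grid: HeatmapGrid,
    cutoff: float = SYNCHRONY_CUTOFF,
) -> list[tuple[float, float]]:
    """Lowest drive at which each g_syn column first turns synchronous.

    Scans each column in ascending I_mu for the first cell with
    S_before > cutoff; columns with no synchronous cell are omitted.
    Returns (g_syn, I_mu) pairs forming the border polyline.
    """
    border = []
    for gi, g in enumerate(grid.g_syn_values):
        col = grid.S_before[gi, :]
        above = np.where(col > cutoff)[0]
        if above.size:
            border.append((g, grid.I_mu_values[int(above[0])]))
    return border
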