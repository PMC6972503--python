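"""Plain-text readers and writers for rasters, networks and heatmaps.

All formats are tab-delimited text with a single header line, so every
artifact round-trips through the paired reader and is diffable and
greppable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import Connectivity
from .raster import SpikeRaster
from .sweep import HeatmapGrid

__all__ = [
    "write_raster", "read_raster",
    "write_edges", "read_edges",
    "write_drive", "read_drive",
    "write_heatmap_panel", "read_heatmap_matrix",
]


def write_raster(raster: SpikeRaster, path: str | Path) -> None:
    df = pd.DataFrame({"neuron_id": raster.neuron_ids, "spike_time_ms": raster.times})
    df.to_csv(path, sep="\t", index=False)


def read_raster(path: str | Path, n_neurons: int) -> SpikeRaster:
    df = pd.read_csv(path, sep="\t")
    return SpikeRaster(
        df["neuron_id"].to_numpy(np.int64),
        df["spike_time_ms"].to_numpy(float),
        n_neurons,
    )


def write_edges(conn: Connectivity, path: str | Path) -> None:
    df = pd.DataFrame({"pre_id": conn.pre, "post_id": conn.post})
    df.to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path, N: int) -> Connectivity:
    df = pd.read_csv(path, sep="\t")
    return Connectivity(
        N=N,
        pre=df["pre_id"].to_numpy(np.int64),
        post=df["post_id"].to_numpy(np.int64),
    )


def write_drive(drive: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"I_app_pA": drive}).to_csv(path, sep="\t", index=False)


def read_drive(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["I_app_pA"].to_numpy(float)


def _matrix_frame(grid: HeatmapGrid, M: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        M.T,  # rows indexed by I_mu (heatmap y-axis), columns by g_syn
        index=pd.Index(grid.I_mu_values, name="I_mu_pA"),
        columns=[f"{g:g}" for g in grid.g_syn_values],
    )


def write_heatmap_panel(grid: HeatmapGrid, outdir: str | Path,
                        bistability: float | None = None,
                        border: list | None = None) -> None:
    """Write one panel: matrices as TSV plus a JSON metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, M in [
        ("S_before", grid.S_before),
        ("S_after", grid.S_after),
        ("diff", grid.diff),
        ("mean_firing_frequency", grid.mean_firing_frequency),
    ]:
        _matrix_frame(grid, M).to_csv(outdir / f"{name}.tsv", sep="\t")
    meta = dict(grid.meta)
    meta["g_syn_values"] = list(grid.g_syn_values)
    meta["I_mu_values"] = list(grid.I_mu_values)
    if bistability is not None:
        meta["bistability_measure"] = bistability
    if border is not None:
        meta["synchrony_border"] = border
    (outdir / "panel.json").write_text(json.dumps(meta, indent=2))


def read_heatmap_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a panel matrix TSV; returns (g_syn_values, I_mu_values, matrix).

    The matrix is returned in [g_index, I_index] orientation.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    I_mu = df.index.to_numpy(float)
    g_syn = np.array([float(c) for c in df.columns])
    return g_syn, I_mu, df.to_numpy(float).T
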