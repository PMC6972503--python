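"""Random directed inhibitory-network construction and tonic drive.

Networks are Erdos-Renyi directed graphs without self-edges: each
ordered pair (i, j), i != j, carries a synapse independently with
probability ``p_conn``.  Heterogeneity across cells enters solely
through the tonic drive, drawn i.i.d. from Normal(I_mu, sigma_I**2) and
held fixed for the whole simulation.  Topology, drive and initial
conditions are controlled by independent seeds so each can be varied
while the others stay bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["NetworkConfig", "Connectivity", "build_connectivity", "draw_drive"]


@dataclass(frozen=True)
class NetworkConfig:
    """Network-level parameters of one simulated condition.

    ``N`` cells, connection probability ``p_conn``, uniform synaptic
    weight ``g_syn`` (nS), tonic drive Normal(``I_mu``, ``sigma_I``**2)
    in pA, and three independent RNG seeds (topology, drive, initial
    conditions).
    """

    N: int = 500
    p_conn: float = 0.12
    g_syn: float = 1.25
    I_mu: float = 185.0
    sigma_I: float = 6.0
    seed_topology: int = 0
    seed_drive: int = 1
    seed_init: int = 2

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if not 0.0 <= self.p_conn <= 1.0:
            raise ValueError("p_conn must lie in [0, 1]")
        if self.sigma_I < 0:
            raise ValueError("sigma_I must be non-negative")
        if self.g_syn < 0:
            raise ValueError("g_syn must be non-negative")


@dataclass(frozen=True)
class Connectivity:
    """Directed edge set (presynaptic -> postsynaptic) over N cells."""

    N: int
    pre: np.ndarray   # source index of each edge
    post: np.ndarray  # target index of each edge

    @property
    def n_edges(self) -> int:
        return int(self.pre.size)

    def out_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR layout of out-edges: (indptr, targets) grouped by source."""
        order = np.argsort(self.pre, kind="stable")
        targets = self.post[order].astype(np.int64)
        counts = np.bincount(self.pre, minlength=self.N)
        indptr = np.zeros(self.N + 1, dtype=np.int64)
        np.cumsum(counts, out=indptr[1:])
        return indptr, targets

    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.post, minlength=self.N)

    def to_edge_array(self) -> np.ndarray:
        return np.column_stack([self.pre, self.post])


def build_connectivity(N: int, p_conn: float, seed: int) -> Connectivity:
    """Sample an Erdos-Renyi directed graph with no self-edges.

    Each ordered pair (i, j), i != j, is an edge independently with
    probability ``p_conn``; reproducible under ``seed``.
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    if not 0.0 <= p_conn <= 1.0:
        raise ValueError("p_conn must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random((N, N)) < p_conn
    np.fill_diagonal(mask, False)
    pre, post = np.nonzero(mask)
    return Connectivity(N=N, pre=pre.astype(np.int64), post=post.astype(np.int64))


def draw_drive(N: int, I_mu: float, sigma_I: float, seed: int) -> np.ndarray:
    """Per-cell tonic applied currents, i.i.d. Normal(I_mu, sigma_I**2) pA."""
    if sigma_I < 0:
        raise ValueError("sigma_I must be non-negative")
    rng = np.random.default_rng(seed)
    return rng.normal(I_mu, sigma_I, size=N)
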