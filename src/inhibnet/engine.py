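"""Fixed-step network integration and stimulus protocols.

The full protocol: every simulation runs for ``T_total`` ms at Euler
step ``dt`` with initial voltages drawn uniformly from (-70, 0) mV and
u = 0.  Spikes trigger no synaptic transmitter pulse before
``synapse_enable_t`` (initial transients decay unsynaptically).  A
square current pulse of amplitude ``perturb_amplitude`` and width
``perturb_width`` is delivered uniformly to all cells at
``perturb_onset`` to probe for a coexisting synchronous attractor.

The update order within a step is: (1) synaptic currents from the
previous step's gates, (2) Euler update of all cells, (3) resets and
spike recording, (4) gate advance with this step's spikes.  Gates use
their exact closed-form solutions, so only the voltage equations incur
Euler error.

An Ornstein-Uhlenbeck conductance process models fluctuating background
excitatory synaptic input; its excursions motivate a weaker, wider
square pulse (320 pA / 5 ms) used as a physiologically plausible stand-in
for the idealized perturbation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, asdict
from typing import Optional

import numpy as np
from scipy.signal import lfilter

from . import _kernels
from .model import IzhikevichParams, SynapseParams
from .network import Connectivity, NetworkConfig, build_connectivity, draw_drive
from .raster import SpikeRaster

__all__ = [
    "StimulusProtocol",
    "OUParams",
    "SimulationResult",
    "SimulationBlowupError",
    "simulate",
    "simulate_config",
    "ou_conductance",
    "conductance_to_current",
    "make_ou_pulse_protocol",
]

V_INIT_LOW = -70.0
V_INIT_HIGH = 0.0


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing constants and perturbation pulse of one simulation."""

    T_total: float = 2000.0
    dt: float = 0.01
    synapse_enable_t: float = 100.0
    perturb_amplitude: float = 1000.0
    perturb_width: float = 2.0
    perturb_onset: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 < self.dt <= 0.1:
            raise ValueError("dt must lie in (0, 0.1] ms")
        if self.perturb_onset + self.perturb_width > self.T_total:
            raise ValueError("perturbation must end within the simulation")
        if not self.synapse_enable_t < self.perturb_onset:
            raise ValueError("synapses must enable before the perturbation")

    def without_perturbation(self) -> "StimulusProtocol":
        return replace(self, perturb_amplitude=0.0)


def make_ou_pulse_protocol(base: Optional[StimulusProtocol] = None) -> StimulusProtocol:
    """The default protocol with the OU-motivated 320 pA / 5 ms pulse."""
    base = base if base is not None else StimulusProtocol()
    return replace(base, perturb_amplitude=320.0, perturb_width=5.0)


@dataclass(frozen=True)
class OUParams:
    """Ornstein-Uhlenbeck background excitatory conductance parameters.

    Exact-update recursion
    ``g_e(t+h) = g_e0 + [g_e(t) - g_e0] exp(-h/tau_e) + A_e N(0,1)`` with
    ``A_e = sqrt(D_e tau_e / 2 * (1 - exp(-2h/tau_e)))``, giving
    stationary mean ``g_e0`` and variance ``D_e tau_e / 2``.
    """

    g_e0: float = 3.0      # nS
    tau_e: float = 2.0     # ms
    D_e: float = 2.0       # nS^2 / ms (diffusion coefficient)
    h: float = 0.01        # ms
    E_exc: float = 0.0     # mV
    V_ref: float = -60.6   # mV, resting potential used for current conversion

    def __post_init__(self) -> None:
        if self.tau_e <= 0 or self.h <= 0:
            raise ValueError("tau_e and h must be positive")

    @property
    def A_e(self) -> float:
        return math.sqrt(
            (self.D_e * self.tau_e / 2.0) * (1.0 - math.exp(-2.0 * self.h / self.tau_e))
        )


def ou_conductance(ou: OUParams, T: float, seed: int) -> np.ndarray:
    """OU conductance series g_e(0), g_e(h), ..., g_e(T) in nS.

    Uses the exact AR(1) update with initial condition g_e(0) = g_e0;
    reproducible under ``seed``.
    """
    n = int(round(T / ou.h))
    rng = np.random.default_rng(seed)
    E = math.exp(-ou.h / ou.tau_e)
    noise = ou.A_e * rng.standard_normal(n)
    # deviation from the mean follows y[k] = E y[k-1] + noise[k], y[0] = 0
    dev = lfilter([1.0], [1.0, -E], noise)
    out = np.empty(n + 1)
    out[0] = ou.g_e0
    out[1:] = ou.g_e0 + dev
    return out


def conductance_to_current(g: float | np.ndarray, ou: OUParams) -> float | np.ndarray:
    """Depolarizing current (pA) equivalent to conductance ``g`` (nS).

    The conductance multiplies the driving force |V_ref - E_exc| with V
    approximated at the resting potential; returned positive so it can be
    delivered through the applied-current channel.
    """
    return g * abs(ou.V_ref - ou.E_exc)


@dataclass(frozen=True)
class SimulationResult:
    """Raster plus full provenance of one network integration."""

    raster: SpikeRaster
    config: NetworkConfig
    protocol: StimulusProtocol
    neuron_params: IzhikevichParams
    synapse_params: SynapseParams
    V_samples: Optional[np.ndarray] = None
    V_sample_times: Optional[np.ndarray] = None


class SimulationBlowupError(RuntimeError):
    """Raised when a membrane potential leaves +-1000 mV (numerical blow-up)."""

    def __init__(self, neuron: int, t: float):
        self.neuron = neuron
        self.t = t
        super().__init__(
            f"membrane potential of neuron {neuron} left +-1000 mV at t = {t:.3f} ms"
        )


def _initial_state(N: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    V0 = rng.uniform(V_INIT_LOW, V_INIT_HIGH, size=N)
    u0 = np.zeros(N)
    return V0, u0


def simulate(
    config: NetworkConfig,
    p: IzhikevichParams,
    sp: Optional[SynapseParams] = None,
    proto: Optional[StimulusProtocol] = None,
    connectivity: Optional[Connectivity] = None,
    drive: Optional[np.ndarray] = None,
    sample_voltage_every: Optional[float] = None,
) -> SimulationResult:
    """Integrate one network under the given protocol.

    Topology, drive and initial conditions default to fresh draws from
    the three seeds in ``config``; precomputed ``connectivity`` / ``drive``
    may be supplied instead (e.g. to reuse a topology across protocols).
    ``sample_voltage_every`` (ms) optionally stores voltage snapshots on a
    coarse grid.
    """
    sp = sp if sp is not None else SynapseParams(g_syn=config.g_syn)
    if sp.g_syn != config.g_syn:
        sp = sp.with_weight(config.g_syn)
    proto = proto if proto is not None else StimulusProtocol()

    conn = connectivity if connectivity is not None else build_connectivity(
        config.N, config.p_conn, config.seed_topology
    )
    if conn.N != config.N:
        raise ValueError("connectivity size does not match config.N")
    I_app = drive if drive is not None else draw_drive(
        config.N, config.I_mu, config.sigma_I, config.seed_drive
    )
    I_app = np.ascontiguousarray(I_app, dtype=np.float64)
    if I_app.size != config.N:
        raise ValueError("drive vector length does not match config.N")
    if not np.all(np.isfinite(I_app)):
        raise ValueError("non-finite entries in drive vector")

    V, u = _initial_state(config.N, config.seed_init)
    indptr, targets = conn.out_csr()

    n_steps = int(round(proto.T_total / proto.dt))
    # spike capacity: absolute refractoriness is one step, but 1 kHz per
    # cell is far beyond these dynamics; grow on overflow just in case
    cap = max(100_000, int(config.N * proto.T_total * 1.0))

    sample_stride = 0
    V_samples = np.empty((0, 0))
    sample_times = None
    if sample_voltage_every is not None:
        sample_stride = max(1, int(round(sample_voltage_every / proto.dt)))
        n_samples = n_steps // sample_stride
        V_samples = np.empty((n_samples, config.N))
        sample_times = (np.arange(1, n_samples + 1) * sample_stride) * proto.dt

    while True:
        spike_ids = np.empty(cap, dtype=np.int64)
        spike_times = np.empty(cap, dtype=np.float64)
        status, n_sp, bad_neuron, bad_t = _kernels.integrate_network(
            V.copy(), u.copy(), I_app,
            indptr, targets,
            p.C_m, p.v_r, p.v_t, p.v_peak, p.a, p.b, p.c, p.d, p.k_low, p.k_high,
            sp.g_syn, sp.E_syn, sp.alpha, sp.beta, sp.T_dur,
            proto.dt, n_steps, proto.synapse_enable_t,
            proto.perturb_amplitude, proto.perturb_onset,
            proto.perturb_onset + proto.perturb_width,
            spike_ids, spike_times,
            sample_stride, V_samples,
        )
        if status == _kernels.BLOWUP:
            raise SimulationBlowupError(bad_neuron, bad_t)
        if status == _kernels.SPIKE_OVERFLOW:
            cap *= 4
            continue
        break

    raster = SpikeRaster(
        spike_ids[:n_sp].copy(), spike_times[:n_sp].copy(), config.N
    )
    return SimulationResult(
        raster=raster,
        config=config,
        protocol=proto,
        neuron_params=p,
        synapse_params=sp,
        V_samples=V_samples if sample_stride else None,
        V_sample_times=sample_times,
    )


def simulate_config(
    config: NetworkConfig,
    preset_params: IzhikevichParams,
    proto: Optional[StimulusProtocol] = None,
) -> SimulationResult:
    """Convenience wrapper: simulate straight from a NetworkConfig."""
    return simulate(config, preset_params, proto=proto)
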