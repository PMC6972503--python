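"""Single-neuron and single-synapse dynamics.

The neuron model is a modified Izhikevich two-variable system with a
piecewise quadratic nonlinearity::

    C_m dV/dt = k (V - v_r)(V - v_t) - u - I_syn + I_app + I_perturb
        du/dt = a [ b (V - v_r) - u ]
    if V >= v_peak:  V <- c,  u <- u + d

with ``k = k_low`` for ``V <= v_t`` and ``k = k_high`` otherwise.  Units
are pF, mV, ms, pA and nS throughout, which are mutually consistent
(pF * mV / ms == pA), so no hidden conversions appear anywhere.

Two named parameter presets are provided: ``control`` (a healthy
fast-firing cortical interneuron) and ``four_ap`` (the same cell made
hyperexcitable by 4-Aminopyridine: lower rheobase, stronger
spike-frequency adaptation).

Synapses follow a first-order kinetic scheme: each presynaptic spike
releases a 1 ms square transmitter pulse that drives the open-channel
fraction ``s`` through ds/dt = alpha [T] (1 - s) - beta s, which has
closed-form rise and decay solutions used exactly (no ODE stepping for
gates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from ._kernels import integrate_single_cell

__all__ = [
    "IzhikevichParams",
    "NeuronState",
    "SynapseParams",
    "GateState",
    "PRESET_NAMES",
    "make_preset",
    "neuron_step",
    "gate_update",
    "synaptic_current",
    "single_cell_spike_times",
    "fi_curve",
    "find_rheobase",
]


@dataclass(frozen=True)
class IzhikevichParams:
    """Parameters of the modified Izhikevich interneuron model.

    Attributes
    ----------
    C_m : float
        Membrane capacitance (pF).
    v_r, v_t, v_peak : float
        Resting potential, instantaneous threshold, spike cutoff (mV).
    a : float
        Recovery time constant (1/ms).
    b : float
        Sensitivity of the recovery current to subthreshold V (nS).
    c : float
        Post-spike reset voltage (mV).
    d : float
        After-spike recovery-current increment (pA).
    k_low, k_high : float
        Sub-/supra-threshold quadratic scaling (nS/mV).
    """

    C_m: float
    v_r: float
    v_t: float
    v_peak: float
    a: float
    b: float
    c: float
    d: float
    k_low: float
    k_high: float

    def __post_init__(self) -> None:
        if not (self.C_m > 0 and self.k_low > 0 and self.k_high > 0 and self.a > 0):
            raise ValueError("C_m, k_low, k_high and a must all be positive")
        if not (self.v_r < self.v_t < self.v_peak):
            raise ValueError("require v_r < v_t < v_peak")
        if not self.c < self.v_peak:
            raise ValueError("reset voltage c must lie below v_peak")


_PRESETS = {
    "control": IzhikevichParams(
        C_m=73.0, v_r=-60.6, v_t=-43.1, v_peak=2.5,
        a=0.01, b=-0.2, c=-67.0, d=0.75, k_low=0.6, k_high=2.0,
    ),
    "four_ap": IzhikevichParams(
        C_m=49.0, v_r=-60.6, v_t=-43.1, v_peak=2.5,
        a=0.01, b=-0.4, c=-67.0, d=1.25, k_low=0.4, k_high=2.0,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def make_preset(name: str) -> IzhikevichParams:
    """Return the named cell-parameter preset (``control`` or ``four_ap``)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid presets are {sorted(_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class NeuronState:
    """Membrane potential V (mV) and recovery current u (pA)."""

    V: float
    u: float


@dataclass(frozen=True)
class SynapseParams:
    """First-order kinetic synapse parameters.

    ``alpha`` is the inverse rise time (1/ms), ``beta`` the inverse decay
    time (1/ms) and ``T_dur`` the transmitter pulse duration (ms).  The
    derived quantities ``s_inf = alpha / (alpha + beta)`` and
    ``tau_s = 1 / (alpha + beta)`` govern the rise phase.
    """

    g_syn: float = 1.0
    E_syn: float = -75.0
    alpha: float = 3.7037
    beta: float = 0.3333
    T_dur: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be positive")
        if self.g_syn < 0:
            raise ValueError("g_syn must be non-negative")
        if self.T_dur <= 0:
            raise ValueError("T_dur must be positive")

    @property
    def s_inf(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def tau_s(self) -> float:
        return 1.0 / (self.alpha + self.beta)

    def with_weight(self, g_syn: float) -> "SynapseParams":
        return replace(self, g_syn=g_syn)


@dataclass(frozen=True)
class GateState:
    """State of one presynaptic gate.

    ``s`` is the open-channel fraction; ``t_last_spike`` the onset time of
    the most recent transmitter pulse (None before any spike); ``s_at_onset``
    the gate value when that pulse began (the rise integrates from it).
    """

    s: float = 0.0
    t_last_spike: Optional[float] = None
    s_at_onset: float = 0.0
    t: float = 0.0


def neuron_step(
    state: NeuronState,
    p: IzhikevichParams,
    I_total: float,
    dt: float,
) -> tuple[NeuronState, bool]:
    """One forward-Euler step of the neuron equations.

    ``I_total`` is the signed sum I_app + I_perturb - I_syn.  The
    quadratic scaling ``k`` is chosen from the pre-step voltage (k_low for
    V <= v_t).  The reset is applied after the update: if the updated V
    reaches ``v_peak`` the neuron is said to have spiked, V is set to
    ``c`` and u incremented by ``d``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (math.isfinite(state.V) and math.isfinite(state.u) and math.isfinite(I_total)):
        raise ValueError("non-finite neuron state or input current")
    k = p.k_low if state.V <= p.v_t else p.k_high
    dV = (k * (state.V - p.v_r) * (state.V - p.v_t) - state.u + I_total) / p.C_m
    du = p.a * (p.b * (state.V - p.v_r) - state.u)
    V = state.V + dt * dV
    u = state.u + dt * du
    if V >= p.v_peak:
        return NeuronState(V=p.c, u=u + p.d), True
    return NeuronState(V=V, u=u), False


def gate_rise(s0: float, elapsed: float, sp: SynapseParams) -> float:
    """Closed-form gate value ``elapsed`` ms into a transmitter pulse."""
    return sp.s_inf + (s0 - sp.s_inf) * math.exp(-elapsed / sp.tau_s)


def gate_decay(s1: float, elapsed: float, sp: SynapseParams) -> float:
    """Closed-form gate value ``elapsed`` ms after the pulse ended."""
    return s1 * math.exp(-sp.beta * elapsed)


def gate_update(
    g: GateState,
    sp: SynapseParams,
    t_now: float,
    presyn_spiked: bool = False,
) -> GateState:
    """Advance one gate to ``t_now`` using the closed-form solutions.

    Within ``T_dur`` of the last presynaptic spike the gate follows the
    exponential rise toward ``s_inf``; afterwards it decays at rate
    ``beta``.  A new presynaptic spike at ``t_now`` restarts the pulse
    clock with the current gate value as the rise's initial condition
    (continuity is preserved for overlapping pulses).
    """
    if not math.isfinite(t_now):
        raise ValueError("non-finite time")
    if t_now < g.t:
        raise ValueError("time must advance monotonically between gate updates")
    if g.t_last_spike is None:
        s = g.s  # no pulse yet: gate has never opened, stays at its value (0)
        onset, s_onset = g.t_last_spike, g.s_at_onset
    else:
        t_end = g.t_last_spike + sp.T_dur
        if t_now <= t_end:
            s = gate_rise(g.s_at_onset, t_now - g.t_last_spike, sp)
        else:
            s_end = gate_rise(g.s_at_onset, sp.T_dur, sp)
            s = gate_decay(s_end, t_now - t_end, sp)
        onset, s_onset = g.t_last_spike, g.s_at_onset
    if presyn_spiked:
        onset, s_onset = t_now, s
    return GateState(s=s, t_last_spike=onset, s_at_onset=s_onset, t=t_now)


def synaptic_current(
    V_post: float,
    s_values: Sequence[float] | np.ndarray,
    g_syn: float,
    E_syn: float,
    adjacency_in: Iterable[int],
) -> float:
    """Total synaptic current onto one cell, I_syn = sum g_syn s_j (V - E_syn).

    ``s_values`` holds one gate value per presynaptic source (all outgoing
    synapses of a cell share its gate); ``adjacency_in`` lists the source
    indices with an edge onto the postsynaptic cell.  The returned value is
    positive for V above the reversal potential and enters the voltage
    equation with a minus sign (hyperpolarizing for inhibitory synapses).
    """
    s = np.asarray(s_values, dtype=float)
    idx = np.fromiter(adjacency_in, dtype=np.int64)
    if idx.size == 0:
        return 0.0
    return float(g_syn * (V_post - E_syn) * s[idx].sum())


def single_cell_spike_times(
    p: IzhikevichParams,
    I_app: float,
    T: float = 2000.0,
    dt: float = 0.01,
    V0: Optional[float] = None,
    u0: float = 0.0,
) -> np.ndarray:
    """Spike times (ms) of an isolated neuron under constant drive."""
    if T <= 0 or dt <= 0:
        raise ValueError("T and dt must be positive")
    V0 = p.v_r if V0 is None else V0
    return integrate_single_cell(
        float(V0), float(u0), float(I_app),
        p.C_m, p.v_r, p.v_t, p.v_peak, p.a, p.b, p.c, p.d, p.k_low, p.k_high,
        float(dt), int(round(T / dt)),
    )


def fi_curve(
    p: IzhikevichParams,
    I_values: Sequence[float],
    T: float = 2000.0,
    dt: float = 0.01,
) -> np.ndarray:
    """Initial and final ISI frequencies versus constant current.

    For each current the neuron is run from rest for ``T`` ms;
    ``f_initial = 1000 / first ISI`` and ``f_final = 1000 / last ISI``
    (Hz).  Currents evoking fewer than two spikes report 0 Hz for both.
    When exactly two spikes occur, the single ISI serves as both.

    Returns a structured array with fields ``I_pA``, ``f_initial_Hz``,
    ``f_final_Hz``.
    """
    I_values = list(I_values)
    if len(I_values) == 0:
        raise ValueError("I_values must be non-empty")
    out = np.zeros(
        len(I_values),
        dtype=[("I_pA", float), ("f_initial_Hz", float), ("f_final_Hz", float)],
    )
    for i, I in enumerate(I_values):
        spikes = single_cell_spike_times(p, I, T=T, dt=dt)
        f_init = f_final = 0.0
        if spikes.size >= 2:
            f_init = 1000.0 / (spikes[1] - spikes[0])
            f_final = 1000.0 / (spikes[-1] - spikes[-2])
        out[i] = (I, f_init, f_final)
    return out


def find_rheobase(
    p: IzhikevichParams,
    tol: float = 0.5,
    T: float = 2000.0,
    dt: float = 0.01,
    I_max: float = 1000.0,
) -> float:
    """Smallest constant current evoking at least one spike within ``T`` ms.

    Bisection on the bracket (0, I_max); returns the midpoint of the final
    bracket, accurate to within ``tol`` pA.  Raises if even ``I_max``
    evokes no spike.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")

    def spikes_at(I: float) -> bool:
        return single_cell_spike_times(p, I, T=T, dt=dt).size >= 1

    lo, hi = 0.0, I_max
    if not spikes_at(hi):
        raise ValueError(f"no spiking found for currents up to {I_max} pA")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if spikes_at(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
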