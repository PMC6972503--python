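"""Numba-compiled integration kernels.

These implement the forward-Euler update of the network, with the
synaptic gates advanced by their exact piecewise-exponential solutions.
The per-step cost is kept near O(N) by tracking, for every postsynaptic
cell, the running sum of its incoming gate values: outside a transmitter
pulse every gate decays by the same factor exp(-beta*dt), so the sums
can be decayed wholesale and corrected only along the out-edges of the
(few) sources currently inside a pulse.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the network kernel
OK = 0
BLOWUP = 1
SPIKE_OVERFLOW = 2


@njit(cache=True)
def integrate_single_cell(V0, u0, I_app,
                          C_m, v_r, v_t, v_peak, a, b, c, d, k_low, k_high,
                          dt, n_steps):
    """Euler-integrate one neuron under constant drive; return spike times."""
    V = V0
    u = u0
    # generous cap: one spike per step is the physical maximum
    spikes = np.empty(min(n_steps, 4_000_000), np.float64)
    n = 0
    for step in range(n_steps):
        k = k_low if V <= v_t else k_high
        Vn = V + dt * (k * (V - v_r) * (V - v_t) - u + I_app) / C_m
        un = u + dt * a * (b * (V - v_r) - u)
        if Vn >= v_peak:
            V = c
            u = un + d
            spikes[n] = (step + 1) * dt
            n += 1
        else:
            V = Vn
            u = un
    return spikes[:n].copy()


@njit(cache=True)
def integrate_network(V, u, I_app,
                      out_indptr, out_indices,
                      C_m, v_r, v_t, v_peak, a, b, c, d, k_low, k_high,
                      g_syn, E_syn, alpha, beta, T_dur,
                      dt, n_steps, syn_enable_t,
                      perturb_amp, perturb_onset, perturb_end,
                      spike_ids, spike_times,
                      sample_stride, V_samples):
    """Integrate the full network in place.

    Parameters are flat scalars/arrays for numba friendliness.  ``V`` and
    ``u`` are modified in place.  Spikes are written into the preallocated
    ``spike_ids`` / ``spike_times`` buffers.  If ``sample_stride > 0``,
    voltage snapshots are stored every ``sample_stride`` steps into
    ``V_samples`` (shape (n_samples, N)).

    Returns (status, n_spikes, bad_neuron, bad_time).
    """
    N = V.size
    s_inf = alpha / (alpha + beta)
    tau_s = 1.0 / (alpha + beta)
    decay = np.exp(-beta * dt)

    s = np.zeros(N)            # gate value of each source cell
    in_pulse = np.zeros(N, np.uint8)
    pulse_t0 = np.zeros(N)     # onset time of current pulse
    s_at_t0 = np.zeros(N)      # gate value at that onset
    syn_in = np.zeros(N)       # sum of incoming gate values per cell

    max_spikes = spike_ids.size
    n_sp = 0
    n_sampled = 0

    for step in range(n_steps):
        t_next = (step + 1) * dt
        t_now = step * dt

        perturbing = (t_now >= perturb_onset) and (t_now < perturb_end)

        # (1)+(2): currents from previous-step gates, Euler update, resets
        for i in range(N):
            I = I_app[i] - g_syn * syn_in[i] * (V[i] - E_syn)
            if perturbing:
                I += perturb_amp
            k = k_low if V[i] <= v_t else k_high
            Vn = V[i] + dt * (k * (V[i] - v_r) * (V[i] - v_t) - u[i] + I) / C_m
            un = u[i] + dt * a * (b * (V[i] - v_r) - u[i])
            if Vn >= v_peak:
                V[i] = c
                u[i] = un + d
                if n_sp >= max_spikes:
                    return SPIKE_OVERFLOW, n_sp, i, t_next
                spike_ids[n_sp] = i
                spike_times[n_sp] = t_next
                n_sp += 1
                # (4a) new pulse starts at t_next, handled after gate advance
                # mark via a sentinel in in_pulse: 2 = spiked this step
                in_pulse[i] |= 2
            else:
                if Vn > 1e3 or Vn < -1e3:
                    return BLOWUP, n_sp, i, t_next
                V[i] = Vn
                u[i] = un

        # (4) advance gates from t_now to t_next; maintain incoming sums.
        # Wholesale decay first: syn_in_new = decay * syn_in_old + corrections,
        # where the correction for source j is s_j_new - decay * s_j_old
        # (zero for any source outside a transmitter pulse).
        for i in range(N):
            syn_in[i] *= decay
        for i in range(N):
            flag = in_pulse[i]
            active = (flag & 1) == 1
            spiked = (flag & 2) == 2
            s_old = s[i]
            if active:
                t_end = pulse_t0[i] + T_dur
                if t_next < t_end - 1e-12:
                    s_new = s_inf + (s_at_t0[i] - s_inf) * np.exp(-(t_next - pulse_t0[i]) / tau_s)
                else:
                    s_end = s_inf + (s_at_t0[i] - s_inf) * np.exp(-T_dur / tau_s)
                    s_new = s_end * np.exp(-beta * (t_next - t_end))
                    in_pulse[i] = flag & 2
                    active = False
            else:
                s_new = s_old * decay

            if spiked and t_next >= syn_enable_t:
                # restart pulse clock; gate continuous at t_next
                in_pulse[i] = 1
                pulse_t0[i] = t_next
                s_at_t0[i] = s_new
            elif spiked:
                in_pulse[i] = in_pulse[i] & 1  # pre-enable spike: no pulse

            if s_new != s_old:
                s[i] = s_new

            ds = s_new - s_old * decay
            if ds != 0.0:
                for e in range(out_indptr[i], out_indptr[i + 1]):
                    syn_in[out_indices[e]] += ds

        if sample_stride > 0 and (step + 1) % sample_stride == 0:
            for i in range(N):
                V_samples[n_sampled, i] = V[i]
            n_sampled += 1

    return OK, n_sp, -1, 0.0
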