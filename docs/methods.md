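# Methods

## The model

`inhibnet` simulates randomly connected networks of inhibitory cortical
interneurons and quantifies when such a network is *bistable*: a stable
asynchronous firing state coexisting with a stable synchronous one, such
that a brief perturbation — not a permanent change in drive — switches
the network into coherent, faster firing. The comparison of interest is
between a healthy interneuron (`control`) and one made hyperexcitable by
the potassium-channel blocker 4-Aminopyridine (`four_ap`), a standard
acute seizure model. The hyperexcitable preset has a lower rheobase,
steeper excitability, and stronger spike-frequency adaptation.

### Single cell

Each cell is a modified Izhikevich two-variable model,

```
C_m dV/dt = k (V - v_r)(V - v_t) - u - I_syn + I_app + I_perturb
    du/dt = a [ b (V - v_r) - u ]
if V >= v_peak:  V <- c,  u <- u + d
```

with `k = k_low` for `V <= v_t` (evaluated at the pre-step voltage, with
the boundary assigned to the subthreshold branch) and `k = k_high`
above. Units are pF, mV, ms, pA, nS, which are mutually consistent
(pF·mV/ms = pA); the code performs no hidden conversions. Preset values:

| parameter | control | four_ap | units |
|-----------|---------|---------|-------|
| C_m       | 73      | 49      | pF    |
| v_r       | −60.6   | −60.6   | mV    |
| v_t       | −43.1   | −43.1   | mV    |
| v_peak    | 2.5     | 2.5     | mV    |
| a         | 0.01    | 0.01    | 1/ms  |
| b         | −0.2    | −0.4    | nS    |
| c         | −67     | −67     | mV    |
| d         | 0.75    | 1.25    | pA    |
| k_low     | 0.6     | 0.4     | nS/mV |
| k_high    | 2       | 2       | nS/mV |

With these values the measured rheobase is ≈ 44 pA (control) and
≈ 27 pA (four_ap), and at matched suprathreshold drive the
hyperexcitable cell fires faster, with `f_final ≤ f_initial`
(adaptation), both checked against a 20× finer-step integration.

### Synapse

Synapses are inhibitory (`E_syn = −75 mV`) and first-order kinetic: a
presynaptic spike releases a unit transmitter pulse `[T] = 1` lasting
1 ms, driving the open-channel fraction through
`ds/dt = alpha [T] (1 - s) - beta s` with `alpha = 3.7037/ms` (fast
rise) and `beta = 0.3333/ms` (≈ 3 ms decay). Within a pulse the gate
follows its closed-form exponential approach to
`s_inf = alpha/(alpha+beta)`; outside, pure exponential decay. Gates are
therefore exact — only the voltage equations incur Euler error. All
outgoing synapses of a cell share its gate (mathematically identical to
per-edge gates, O(N) state instead of O(N²)), and a spike arriving
during an active pulse restarts the pulse clock with the current gate
value, preserving continuity. The synaptic current onto cell *i* is
`I_syn = g_syn (V_i - E_syn) * sum_j s_j` over presynaptic sources *j*,
with a single network-wide weight `g_syn`.

### Network and drive

Networks are directed Erdős–Rényi graphs over N = 500 cells (no
self-edges; each ordered pair connected independently with probability
`p_conn` ∈ 0.04–0.16). Heterogeneity enters only through the tonic
drive, drawn once per cell from Normal(`I_mu`, `sigma_I`²) with
`sigma_I` ∈ {3, 6, 12} pA, standing in for the aggregate excitatory
input from pyramidal cells. Draws are kept as drawn (no clipping of
rare negative values). Topology, drive and initial conditions use three
independent seeds, so each ingredient can be varied with the others held
bit-identical.

### Protocol

Simulations run 2000 ms with forward Euler at dt = 0.01 ms. Initial
voltages are uniform on (−70, 0) mV (the minimal-assumption reading of
"randomized on (−70, 0)"), u(0) = 0. Spikes trigger no transmitter pulse
before t = 100 ms, letting initial transients decay unsynaptically (the
spikes themselves are kept). At t = 1000 ms every cell receives a square
current pulse — by default 1000 pA for 2 ms, an idealized kick that
forces near-instantaneous population spiking. Synchrony is scored on
500–1000 ms ("random initial conditions") and 1500–2000 ms ("following
perturbation"). The per-step update order is: synaptic currents from the
previous step's gates; Euler update of all cells; resets and spike
recording (spike time = end of step); gate advance including this
step's spikes. A guard aborts with diagnostics if any voltage leaves
±1000 mV between reset checks.

The physiologically motivated variant replaces the pulse with 320 pA for
5 ms: an Ornstein–Uhlenbeck model of background excitatory conductance
(exact AR(1) update, `g_e0 = 3 nS`, `tau_e = 2 ms`, `D_e = 2`,
`h = 0.01 ms`; stationary mean 3 nS and variance `D_e tau_e / 2 = 2 nS²`)
produces brief excursions of roughly this size once converted to current
by multiplying by the driving force at rest (|−60.6 − 0| mV, so
1 nS ≈ 60.6 pA). Only the perturbation is replaced; the tonic drive
remains the deterministic per-cell constant.

## Measures

**Synchrony.** Each cell's in-window spike train is convolved with a
Gaussian kernel to give a smooth trace; the measure is the variance of
the population-mean trace divided by the mean per-cell trace variance
(0 = asynchrony, 1 = identical traces). Numerical choices: kernel SD
2 ms (a free parameter of the measure; chosen on the order of the
synaptic rise time so gamma-band coincidence is resolved, and exposed as
a parameter — a regression test bounds the grid-step sensitivity at
0.02), evaluation grid 0.5 ms, kernel truncated at ±5 SD, variances as
discrete time averages over the grid. Only spikes inside the half-open
window contribute: padding by the kernel reach would leak the
synchronized perturbation response at ~1001 ms into the pre-perturbation
window. Cells silent in the window are excluded from the denominator
(including them would inflate the ratio without bound) and their count
is reported; an entirely silent window leaves the measure undefined
(NaN), never silently zero.

**Bistability.** For a (g_syn × I_mu) panel, the per-cell seed-averaged
difference S_after − S_before is computed; entries strictly exceeding
0.3 are summed (values, not counts, so larger transitions weigh more).
The 0.3 threshold separates genuine state changes from mere "tightening"
of already-coherent firing. Undefined cells are skipped and tallied.

**Firing rate.** Total spikes in a window / N / window length, in Hz,
reported for the random-initial-conditions window (500–1000 ms).

**Classification and sharpness.** A state is synchronous iff S > 0.25
(strict at the boundary). Transition sharpness along a drive sweep at
fixed g_syn is the slope between the first point exceeding half the
panel-wide maximum S and the point one current step earlier; undefined
if no point qualifies or the first point already does. Because the
slope scales with the (unpublished) current step of the original
sweeps, absolute slope values are not comparable across studies — only
used relatively, between presets on a common grid.

## Sweeps and seeds

Each grid cell runs n_seeds independent simulations with fresh topology,
drive and initial conditions; the three seeds per replicate are derived
from `(master_seed, g_index, I_index, replicate)` through a
counter-based seed sequence, so cells are order-independent and the
whole grid is reproducible bit for bit. Per-seed values are retained so
every averaged matrix can be recomputed from its audit trail.

Problem sizes used by the test suite and the reproduction script were
chosen to keep a full run desk-sized: the worked-example comparison uses
the full study conditions (N = 500, 2000 ms, 5 replicates); zoomed
bistability panels use a 6 × 8 grid with 3 replicates at the reference
condition (p = 0.12, σ = 6 pA) and 4 × 6 grids with 2 replicates for the
other connectivity/heterogeneity conditions, centred on the published
example point (1.25 nS, 185 pA) since the original zoom axes are not
printed; transition-sharpness scans cover I_mu 100–400 pA in 15 pA steps
at g_syn ∈ {1.0, 1.25} nS.

## What the synthetic rasters do and do not show

The fixture generators (perfectly synchronous, jittered, Poisson,
clustered, silent) produce spike rasters with known coherence so the
measures can be validated against closed-form and brute-force oracles
independently of the simulator. They emulate the statistical structure
of the dynamical regimes, not the dynamics: passing measure tests on
fixtures says nothing about network behavior, which is tested separately
against the simulator itself.

## Known limitations

- Forward Euler at dt = 0.01 ms accumulates spike-time phase drift
  linearly (order 0.01–0.05 ms per spike), so single-cell spike trains
  agree with a fine-step reference in rate and early spike times but not
  per-spike at late times. Network-level statistics are insensitive to
  this at the tested step sizes.
- The example parameter point (1.25 nS, 185 pA) sits near the edge of
  the bistable regime: roughly 9 in 10 network realizations transition
  after the pulse (per-replicate ΔS ≈ 0.38 ± 0.07 over 25 replicates),
  so 5-replicate averages of the transition size fluctuate around the
  0.3 threshold across master seeds.
- No synaptic delays, no gap junctions, no excitatory population, no
  depolarizing GABA; connectivity is homogeneous Erdős–Rényi. These
  match the modeling scope, not cortical reality.
- The Gaussian kernel SD of the synchrony measure is a free parameter;
  absolute S values (and hence the area of the bistable regime, though
  not its control/4-AP ordering) depend on it.
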