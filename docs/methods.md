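# Methods

This note documents the models, the numerical schemes, the parameter
choices, and the design decisions taken where the problem was genuinely
open. It records what the simulations do and do not show; every number
quoted here is computed by the test suite or by `scripts/acceptance.py`.

## Firing-rate model

Each module is a recurrent network of `N` rate neurons. Neuron `i` carries
an activation `x_i` obeying

    tau dx_i/dt = -x_i + g * sum_j J_ij r_j + (inter-module input),

with membrane time constant `tau = 10 ms` and recurrent weights `J_ij`
drawn i.i.d. from N(0, 1/N) — no Dale separation; about half the
connections are excitatory and half inhibitory. Rates are
`r_i = R(x_i)` with the piecewise-saturating transfer

    R(x) = r0 + (rmax - r0) tanh(x / (rmax - r0))   for x >= 0
    R(x) = r0 + r0 tanh(x / r0)                     for x <  0

(background rate `r0 = 0.1`, maximum `rmax = 1.0`; continuous with unit
slope at the origin, strictly increasing, range (0, rmax)). With `g = 0`
the network relaxes to the background rate exactly; for `g > 1` the
balanced random connectivity sustains irregular rate fluctuations whose
population mean grows with `g`. The working range is `1 < g <= 2.5`.

**Inter-module coupling.** Long-range cortico-cortical projections are
excitatory, so the default cross-module weights are uniform positive
`g_ext / N`: module `a` receives `g_ext * <r>_b` — the mean rate of the
other module — as a common depolarizing drive. This matters structurally:
with zero-mean random cross-weights the coupling would act only through the
input *variance* (~ g^2 + g_ext^2), making activity flat in `g_ext` near
zero, whereas the excitatory mean drive makes activity decline steeply as
the last couplings are removed — the behaviour the disconnection studies
measure. A `inter_kind="gaussian"` option retains the zero-mean ensemble
for comparison. The fully-coupled baseline is `g_ext = 1` (unit total
inter-module gain); sweeps descend from there to 0, with the 24%-reduced
point `g_ext = 0.76` kept on the grid.

**Integration.** Classical fixed-step RK4 with `dt = 0.5 ms`
(`dt/tau = 0.05`); a forward-Euler cross-check at `dt = 0.1 ms` agrees in
steady mean rate to better than 1% (tested). Activations start from i.i.d.
N(0, 1) values; the steady-state statistics are insensitive to the start.
Divergence (|x| beyond 1e6) raises an integration error naming `g` and
`dt`. The activity readout is the population-mean rate averaged over the
final third of the run (`t_total = 2000 ms` by default, 1500 ms in the
batched study runs; the chaotic rate fluctuations decorrelate within tens
of ms, so the window holds dozens of correlation times); stationarity of
the window is checked by comparing its halves.

**Batched sweeps.** All (g, g_ext) conditions of one seed share the weight
draw and the initial state and advance together through one set of matrix
products per RK4 stage (`simulate_rate_batch`), in float32 for the large
study runs (float64 agrees to ~1e-6 in the mean rate). Comparisons across
coupling levels are therefore paired, removing weight-sampling noise from
the decrease estimates.

## Conductance-based integrate-and-fire model

Membrane potentials are normalized: rest and reset at 0, threshold 1,
excitatory reversal `V_E = 14/3`, inhibitory reversal `V_I = -2/3`. The
membrane equation (conductances normalized by capacitance, units 1/ms) is

    dV/dt = -g_L V - G_E(t) (V - V_E) - G_I(t) (V - V_I),

with leak `g_L = 0.05/ms`. On crossing threshold the neuron spikes, `V` is
reset to 0 and clamped for an absolute refractory period of 5 ms while its
synaptic input state keeps evolving. Each module holds 80% excitatory and
20% inhibitory neurons; whether a synapse injects into `G_E` or `G_I` is
decided by the presynaptic neuron's type.

**Synapses.** Every spike contributes an alpha kernel
`sigma(t) = (t / tau^2) exp(-t / tau)` scaled by the connection strength:
unit time integral (so `S` is the total conductance-time delivered per
spike), peak `1/(e tau)` at `t = tau`; `tau_E = 1 ms`, `tau_I = 5/3 ms`.
The kernel is realized as a critically damped linear filter whose state is
propagated exactly across each step, so kernel dynamics introduce no
discretization error. Connectivity is Bernoulli over ordered pairs
(self-edges allowed; their effect is O(F/N)): probability `F`, strength `S`
within a module, `F_ext`, `S_ext` across modules (constant strengths — no
spatial profile). An optional flag restricts cross-module projections to
excitatory presynaptic neurons; a recorded `(rows, cols)` geometry is
provenance only.

**Conduction delays.** Each synapse carries a latency drawn uniformly from
[0.5, 3] ms by default. This is the one ingredient added beyond the
textbook description, and it is load-bearing: with strictly zero delay the
model has *no* self-sustained state at these parameters. We verified this
three ways: (i) initializing the network inside the asynchronous state at
its self-consistent rate, the population oscillation grows and activity
collapses within ~40 ms; (ii) a fully synchronized population cannot
re-ignite, because the alpha-kernel tail that survives the shared 5 ms
refractory period carries only ~0.23 of the charge needed to reach
threshold; (iii) staggered cluster states are not self-consistent, since
any excitable neuron responds to a population burst within 1–2 ms. A
spread of synaptic latencies decorrelates burst feedback and stabilizes the
asynchronous state robustly: the measured rate is insensitive to the delay
distribution (0.5–3, 0–5, 1–6 and 2–8 ms all give the same rate to three
figures) and to the drive settings. The zero-delay collapse is itself a
regression test.

**Temporal updating.** A modified second-order Runge–Kutta scheme with
step `dt = 0.1 ms`: exact propagation of the kernel filter states; a Heun
step for `V` using start- and end-of-step conductances; linear
interpolation of the threshold-crossing time within the step; reset and
refractory clamp from the interpolated spike time, with partial-step
integration when the refractory period ends mid-step. Deliveries landing
inside the current step are applied exactly at the interpolated arrival
time; later arrivals are scheduled on the step grid (quantization <= dt/2)
through a ring buffer. Halving `dt` changes measured rates by < 2%
(tested); the single-neuron constant-conductance rate matches the
closed-form period `tau_eff ln(V_inf / (V_inf - 1)) + t_ref` to < 1% at
`dt = 0.05 ms`. The spiking engine is a numba kernel; a population of a
few thousand neurons runs a full 1.5 s protocol in seconds.

**Protocol.** Independent per-neuron Poisson trains of excitatory kernel
events (rate 0.5/ms, amplitude 0.06 — chosen so the drive alone fires a
neuron at ~60 Hz) are applied for 500 ms and removed; the network evolves
freely for 500 ms into a self-sustained steady state; spikes are collected
over the next 500 ms. The drive is an initializer only: ±50% changes in
its rate or amplitude move the measured activity by < 3% (tested). A run
whose measurement window is silent, or pinned at the refractory-limited
ceiling of 200 Hz, raises a regime error naming `S` and `F`; the
stationarity of the window is checked by comparing its halves (< 10%
drift).

**Operating point.** The self-sustained rate is set by the per-module
total coupling `K = N * F * S` (it sits at the mean-field self-consistent
rate of the constant-conductance neuron). The reference multi-module
configuration is 3267 neurons per module at `F = 0.3`, `S = 0.00075`
(`K = 0.735` per module); the single-module calibration configuration is
900 neurons at `F = 0.2`, `S = 0.0085`. When module size or connection
fraction is scaled, `S` is re-derived to keep `K` fixed
(`scaled_coupling_strength`), the same re-calibration applied across
network sizes in the size-convergence study. Normalized disconnection
curves are size-converged already at a few hundred neurons per module
(tested at 150/300/600; the desk-scale studies use 900).

## Disconnection experiments

Sweeps descend from the fully-coupled baseline (`F_ext = F`,
`S_ext = S`, or `g_ext = 1`). Reducing the *number* of inter-module
connections deletes each existing cross-module edge independently with the
given probability (an exact-count option exists); reducing the *strength*
scales every cross-module weight; the joint sweep deletes intra- and
inter-module edges with equal probability. Activity is the mean population
rate per module over the measurement window, normalized by the baseline
(maximum) value of the curve; summaries report the percentage decreases at
a 24% reduction (on the grid by construction, interpolated otherwise) and
at full removal. Per-point seeds derive deterministically from the root
seed (`derive_seed`), and curves aggregate 5 seeds by default with
across-seed standard errors.

Structural results of the model family (all tested):

* symmetric modules trace identical normalized curves (< 2 pp spread);
* deleting a fraction of cross-module synapses and scaling their strengths
  by the same factor give the same curve (< 0.05 pointwise) — both remove
  the same total coupling;
* a joint 50% loss of all synapses and a 100% loss of inter-module
  synapses leave the same total coupling per neuron and hence the same
  activity; inter-module-only loss must be complete to produce the
  decrease that a 50% joint loss produces;
* a network starting from a richer inter-module baseline (`F_ext > F`) is
  closer to saturation and shows a *smaller* percentage decrease at the
  24% point than one starting from `F_ext < F`.

## Known limitations

* The stabilized spiking state is asynchronous and sits at the mean-field
  rate for its total coupling (e.g. ~155 Hz at the 900-neuron calibration
  configuration, ~170 Hz at the three-module baseline). Partially
  synchronized states — which some implementations of this model family
  reach, and which run markedly slower because part of the synaptic charge
  arrives inside refractory windows — are not stable attractors here: with
  short homogeneous delays the rate falls (to ~110 Hz at 0.5 ms constant
  latency) but the state sits one step from collapse, so the package does
  not operate there. Because the baseline sits fairly close to the 200 Hz
  refractory ceiling, relative decreases under partial disconnection are
  compressed compared with a slower-running operating point.
* Firing rates are far above cortical rates in vivo — the price of modules
  thousands of times smaller than real cortical areas; only normalized
  changes in activity carry meaning.
* No synaptic plasticity, adaptation, NMDA-type slow conductances,
  conductance noise, or spatial connectivity profiles; inhibition is fast
  and weak (reversal close to rest). Module activity maps to metabolic
  measures only through proportionality of rate and energy use.
* The rate model's inter-module drive uses the mean rate of the source
  module (all-to-all positive weights); a sparse-connection option exists
  but defaults to fully dense.
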