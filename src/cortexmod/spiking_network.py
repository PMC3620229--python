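"""Conductance-based integrate-and-fire network of coupled cortical modules.

Each module holds ``N`` neurons, 80% excitatory and 20% inhibitory by
default.  The membrane potential (normalized so rest = 0 and threshold = 1)
obeys

.. math::

    \\frac{dV}{dt} = -g_L V - G_E(t)\\,(V - V_E) - G_I(t)\\,(V - V_I),

with conductances (units ms^-1, normalized by membrane capacitance) built
from alpha-function kernels: every presynaptic spike at time :math:`t_k`
contributes :math:`S \\, \\sigma(t - t_k)` with
:math:`\\sigma(t) = (t/\\tau^2) e^{-t/\\tau}` (unit time integral, peak at
:math:`t = \\tau`).  A spike is emitted when V crosses threshold; V is reset
to 0 and clamped there for an absolute refractory period while the synaptic
kernel states keep evolving.

Connectivity is random: within a module every ordered neuron pair is
connected with probability ``F`` at constant strength ``S``; across modules
with probability ``F_ext`` at strength ``S_ext``.  Whether a connection is
excitatory or inhibitory is decided by the presynaptic neuron's type.

A run follows a three-phase protocol: independent Poisson conductance drive
to every neuron (default 500 ms) kick-starts the network, the drive is then
removed and the network evolves freely (500 ms) into a self-sustained steady
state, and spikes are collected over a final measurement window (500 ms).
The activity readout is the mean population firing rate per module over that
window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .rate_network import ParameterError, IntegrationError

__all__ = [
    "SpikingModelParams",
    "SimulationProtocol",
    "SynapticGraph",
    "SpikeTrainSet",
    "SpikingResult",
    "RegimeError",
    "alpha_kernel",
    "build_synaptic_graph",
    "delete_edges",
    "scale_inter_strength",
    "run_protocol",
]


class RegimeError(RuntimeError):
    """The network left the stable regime: it died (no spikes in the
    measurement window) or saturated (all neurons at the refractory-limited
    maximum rate)."""


@dataclass(frozen=True)
class SpikingModelParams:
    """Parameters of the integrate-and-fire model (per module).

    Potentials are normalized (rest 0, threshold 1, excitatory reversal 14/3,
    inhibitory reversal -2/3); conductances are normalized by the membrane
    capacitance and carry units of ms^-1.

    ``delay_min``/``delay_max`` bound the per-edge synaptic + axonal
    conduction latency (uniformly distributed, ms).  A spread of latencies is
    what stabilizes the asynchronous self-sustained state after the
    initiating drive is removed: with strictly zero delay the network's
    asynchronous state is linearly unstable and activity collapses after a
    global burst (set ``delay_min = delay_max = 0`` to observe this).
    """

    n_excitatory: int = 720
    n_inhibitory: int = 180
    v_rest: float = 0.0
    v_threshold: float = 1.0
    v_reset: float = 0.0
    v_exc_reversal: float = 14.0 / 3.0
    v_inh_reversal: float = -2.0 / 3.0
    g_leak: float = 0.05
    tau_exc: float = 1.0
    tau_inh: float = 5.0 / 3.0
    t_refractory: float = 5.0
    s_intra: float = 0.0085
    f_intra: float = 0.2
    s_ext: float = 0.0
    f_ext: float = 0.0
    delay_min: float = 0.5
    delay_max: float = 3.0
    dt: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_excitatory < 1 or self.n_inhibitory < 0:
            raise ParameterError("need n_excitatory >= 1 and n_inhibitory >= 0")
        if not (self.v_rest < self.v_threshold <= self.v_exc_reversal):
            raise ParameterError("need v_rest < v_threshold <= v_exc_reversal")
        if not (self.v_inh_reversal < self.v_rest):
            raise ParameterError("need v_inh_reversal < v_rest")
        for name in ("f_intra", "f_ext"):
            f = getattr(self, name)
            if not (0.0 <= f <= 1.0):
                raise ParameterError(f"{name}={f} outside [0, 1]")
        if self.s_intra < 0 or self.s_ext < 0:
            raise ParameterError("coupling strengths must be >= 0")
        for name in ("tau_exc", "tau_inh", "t_refractory", "dt"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if not (0.0 <= self.delay_min <= self.delay_max):
            raise ParameterError("need 0 <= delay_min <= delay_max")
        if self.g_leak <= 0:
            raise ParameterError("g_leak must be > 0")

    @property
    def n_total(self) -> int:
        """Neurons per module."""
        return self.n_excitatory + self.n_inhibitory

    def replace(self, **kwargs) -> "SpikingModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SimulationProtocol:
    """Drive / relax / measure schedule.

    The Poisson drive (``poisson_rate`` events/ms per neuron, each event an
    excitatory alpha kernel of weight ``poisson_amplitude``) only initializes
    the self-sustained state; it is removed ``t_relax`` ms before any data is
    collected, and measured activity is insensitive to its exact settings.
    """

    t_drive: float = 500.0
    t_relax: float = 500.0
    t_measure: float = 500.0
    poisson_rate: float = 0.5
    poisson_amplitude: float = 0.06

    def __post_init__(self) -> None:
        if min(self.t_drive, self.t_relax, self.t_measure) <= 0:
            raise ParameterError("all protocol durations must be > 0")
        if self.poisson_rate < 0 or self.poisson_amplitude < 0:
            raise ParameterError("Poisson drive settings must be >= 0")

    @property
    def t_total(self) -> float:
        return self.t_drive + self.t_relax + self.t_measure

    @property
    def measure_window(self) -> tuple[float, float]:
        return (self.t_drive + self.t_relax, self.t_total)


@dataclass(frozen=True)
class SynapticGraph:
    """Directed synaptic connectivity in CSR form (by presynaptic neuron).

    ``indptr``/``targets``/``strengths``/``delays`` give, for presynaptic
    neuron ``i``, its postsynaptic targets ``targets[indptr[i]:indptr[i+1]]``
    and per-edge strengths and conduction delays (ms).  The kernel class of
    an edge (excitatory vs inhibitory) is the type of the *presynaptic*
    neuron, ``is_excitatory[i]``.
    """

    indptr: np.ndarray
    targets: np.ndarray
    strengths: np.ndarray
    delays: np.ndarray
    is_excitatory: np.ndarray
    module_of: np.ndarray
    n_modules: int
    geometry: tuple[int, int] | None = None

    @property
    def n_neurons(self) -> int:
        return self.indptr.shape[0] - 1

    @property
    def n_per_module(self) -> int:
        return self.n_neurons // self.n_modules

    @property
    def n_edges(self) -> int:
        return int(self.targets.shape[0])

    def edge_is_inter(self) -> np.ndarray:
        """Boolean per edge: does it cross modules?"""
        pre = np.repeat(
            np.arange(self.n_neurons), np.diff(self.indptr)
        )
        return self.module_of[pre] != self.module_of[self.targets]

    def out_degree(self) -> np.ndarray:
        return np.diff(self.indptr)

    def in_degree(self) -> np.ndarray:
        return np.bincount(self.targets, minlength=self.n_neurons)

    def adjacency(self):
        """Iterate edges as (pre, post, strength, kernel_class) tuples."""
        for i in range(self.n_neurons):
            kind = "excitatory" if self.is_excitatory[i] else "inhibitory"
            for e in range(self.indptr[i], self.indptr[i + 1]):
                yield (i, int(self.targets[e]), float(self.strengths[e]), kind)


@dataclass(frozen=True)
class SpikeTrainSet:
    """Spikes of one run: parallel arrays of neuron ids and times (ms)."""

    neuron_ids: np.ndarray
    times: np.ndarray
    t_window: tuple[float, float]

    @property
    def n_spikes(self) -> int:
        return int(self.neuron_ids.shape[0])

    def in_window(self) -> "SpikeTrainSet":
        lo, hi = self.t_window
        sel = (self.times >= lo) & (self.times < hi)
        return SpikeTrainSet(self.neuron_ids[sel], self.times[sel], self.t_window)

    def isi_minimum(self) -> float:
        """Smallest inter-spike interval of any neuron (inf if none)."""
        best = np.inf
        order = np.lexsort((self.times, self.neuron_ids))
        ids, ts = self.neuron_ids[order], self.times[order]
        same = ids[1:] == ids[:-1]
        if same.any():
            best = float(np.min(np.diff(ts)[same]))
        return best


@dataclass(frozen=True)
class SpikingResult:
    """Outcome of one protocol run."""

    spikes: SpikeTrainSet
    module_rates: np.ndarray  # Hz, mean population rate per module (window)
    params: SpikingModelParams
    protocol: SimulationProtocol
    n_modules: int
    stationarity_drift: float = 0.0
    traces: dict = field(default_factory=dict)

    @property
    def overall_rate(self) -> float:
        return float(self.module_rates.mean())


def alpha_kernel(t, tau: float):
    """Alpha-function synaptic conductance kernel.

    sigma(t) = (t / tau^2) exp(-t / tau) for t >= 0, else 0.  Unit time
    integral; maximum 1/(e tau) attained at t = tau.
    """
    if tau <= 0:
        raise ParameterError("tau must be > 0")
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, (t / tau**2) * np.exp(-np.minimum(t, 7e2 * tau) / tau), 0.0)
    return out if out.ndim else float(out)


def build_synaptic_graph(
    params: SpikingModelParams,
    n_modules: int = 1,
    geometry: tuple[int, int] | None = None,
    seed: int = 0,
    inter_excitatory_only: bool = False,
) -> SynapticGraph:
    """Draw the random synaptic graph for ``n_modules`` coupled modules.

    Every ordered intra-module pair (self-edges included; their effect is
    O(F/N)) is connected independently with probability ``f_intra`` at
    strength ``s_intra``; every ordered cross-module pair with probability
    ``f_ext`` at strength ``s_ext``.  With ``inter_excitatory_only`` the
    cross-module projections originate only from excitatory neurons.

    ``geometry = (rows, cols)`` is recorded for provenance (the model keeps
    connection strength spatially constant); if given it must satisfy
    rows * cols == N.
    """
    if n_modules not in (1, 2, 3):
        raise ParameterError("n_modules must be 1, 2 or 3")
    n_mod = params.n_total
    if geometry is not None and geometry[0] * geometry[1] != n_mod:
        raise ParameterError(
            f"geometry {geometry} does not tile N={n_mod} neurons"
        )
    n = n_mod * n_modules
    module_of = np.repeat(np.arange(n_modules), n_mod).astype(np.int32)
    # within each module the first 80% (n_excitatory) are excitatory
    is_exc = np.zeros(n, dtype=np.bool_)
    for m in range(n_modules):
        is_exc[m * n_mod : m * n_mod + params.n_excitatory] = True

    rng = np.random.default_rng(seed)
    indptr = np.zeros(n + 1, dtype=np.int64)
    rows_targets = []
    rows_strengths = []
    # per-target-neuron connection probability and strength for a presyn in
    # module m: f_intra/s_intra inside m, f_ext/s_ext elsewhere
    for i in range(n):
        m = module_of[i]
        p = np.full(n, params.f_ext)
        s = np.full(n, params.s_ext)
        if inter_excitatory_only and not is_exc[i]:
            p[:] = 0.0
        sl = slice(m * n_mod, (m + 1) * n_mod)
        p[sl] = params.f_intra
        s[sl] = params.s_intra
        tgt = np.flatnonzero(rng.random(n) < p).astype(np.int32)
        rows_targets.append(tgt)
        rows_strengths.append(s[tgt])
        indptr[i + 1] = indptr[i] + tgt.shape[0]
    targets = (
        np.concatenate(rows_targets).astype(np.int32)
        if rows_targets
        else np.empty(0, np.int32)
    )
    strengths = (
        np.concatenate(rows_strengths)
        if rows_strengths
        else np.empty(0, float)
    )
    delays = rng.uniform(params.delay_min, params.delay_max, targets.shape[0])
    return SynapticGraph(
        indptr=indptr,
        targets=targets,
        strengths=strengths,
        delays=delays,
        is_excitatory=is_exc,
        module_of=module_of,
        n_modules=n_modules,
        geometry=geometry,
    )


def _rebuild_with_mask(graph: SynapticGraph, keep: np.ndarray) -> SynapticGraph:
    counts = np.zeros(graph.n_neurons, dtype=np.int64)
    pre = np.repeat(np.arange(graph.n_neurons), np.diff(graph.indptr))
    np.add.at(counts, pre[keep], 1)
    indptr = np.zeros(graph.n_neurons + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return SynapticGraph(
        indptr=indptr,
        targets=graph.targets[keep],
        strengths=graph.strengths[keep],
        delays=graph.delays[keep],
        is_excitatory=graph.is_excitatory,
        module_of=graph.module_of,
        n_modules=graph.n_modules,
        geometry=graph.geometry,
    )


def delete_edges(
    graph: SynapticGraph,
    fraction: float,
    seed: int = 0,
    which: str = "inter",
    exact: bool = False,
) -> SynapticGraph:
    """Delete a fraction of edges, modelling loss of synaptic connections.

    ``which`` selects inter-module edges only (disconnection of long-range
    projections), intra-module edges only, or all edges.  By default each
    eligible edge is removed independently with probability ``fraction``
    (seeded); with ``exact`` a round(fraction * n_eligible) subset is removed.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ParameterError("fraction must lie in [0, 1]")
    if which not in ("inter", "intra", "all"):
        raise ParameterError("which must be 'inter', 'intra' or 'all'")
    if fraction == 0.0:
        return graph
    if which == "inter":
        eligible = graph.edge_is_inter()
    elif which == "intra":
        eligible = ~graph.edge_is_inter()
    else:
        eligible = np.ones(graph.n_edges, dtype=bool)
    rng = np.random.default_rng(seed)
    drop = np.zeros(graph.n_edges, dtype=bool)
    idx = np.flatnonzero(eligible)
    if exact:
        k = int(round(fraction * idx.size))
        drop[rng.choice(idx, size=k, replace=False)] = True
    else:
        drop[idx] = rng.random(idx.size) < fraction
    return _rebuild_with_mask(graph, ~drop)


def scale_inter_strength(graph: SynapticGraph, factor: float) -> SynapticGraph:
    """Multiply every inter-module strength by ``factor`` (efficacy loss)."""
    if factor < 0:
        raise ParameterError("factor must be >= 0")
    strengths = graph.strengths.copy()
    inter = graph.edge_is_inter()
    strengths[inter] *= factor
    return SynapticGraph(
        indptr=graph.indptr,
        targets=graph.targets,
        strengths=strengths,
        delays=graph.delays,
        is_excitatory=graph.is_excitatory,
        module_of=graph.module_of,
        n_modules=graph.n_modules,
        geometry=graph.geometry,
    )


def run_protocol(
    params: SpikingModelParams,
    graph: SynapticGraph,
    protocol: SimulationProtocol | None = None,
    seed: int | None = None,
    z_exc_init: np.ndarray | None = None,
    record_traces: bool = False,
    check_regime: bool = True,
) -> SpikingResult:
    """Run the drive / relax / measure protocol and read out module rates.

    Returns the full spike train set plus the mean population firing rate of
    each module (Hz) over the measurement window.  Raises
    :class:`RegimeError` if the network dies or saturates at the
    refractory-limited ceiling, per the stable-state requirement.
    """
    protocol = protocol or SimulationProtocol()
    seed = params.seed if seed is None else seed
    n = graph.n_neurons
    dt = params.dt
    n_steps = int(round(protocol.t_total / dt))
    max_spikes = int(n * (protocol.t_total / params.t_refractory + 2))
    sp_neuron = np.empty(max_spikes, dtype=np.int64)
    sp_time = np.empty(max_spikes)
    if z_exc_init is None:
        z_exc_init = np.zeros(n)
    if record_traces:
        v_trace = np.empty((n_steps + 1, n))
        ge_trace = np.empty((n_steps + 1, n))
        gi_trace = np.empty((n_steps + 1, n))
    else:
        v_trace = np.empty((1, 1))
        ge_trace = np.empty((1, 1))
        gi_trace = np.empty((1, 1))

    count = _kernels.run_network(
        graph.indptr,
        graph.targets,
        graph.strengths,
        graph.delays,
        graph.is_excitatory,
        dt,
        n_steps,
        protocol.t_drive,
        protocol.poisson_rate,
        protocol.poisson_amplitude,
        params.g_leak,
        params.v_exc_reversal,
        params.v_inh_reversal,
        params.tau_exc,
        params.tau_inh,
        params.t_refractory,
        params.v_threshold,
        params.v_reset,
        np.int64(seed % (2**31)),
        z_exc_init,
        sp_neuron,
        sp_time,
        record_traces,
        v_trace,
        ge_trace,
        gi_trace,
    )
    if count == -1:
        raise IntegrationError("spike buffer overflow (network saturated?)")
    if count == -2:
        raise IntegrationError(
            f"membrane potential became non-finite "
            f"(S={params.s_intra}, F={params.f_intra}, dt={dt})"
        )

    lo, hi = protocol.measure_window
    spikes = SpikeTrainSet(
        neuron_ids=sp_neuron[:count].copy(),
        times=sp_time[:count].copy(),
        t_window=(lo, hi),
    )
    win = spikes.in_window()
    n_mod = graph.n_per_module
    counts = np.bincount(
        graph.module_of[win.neuron_ids], minlength=graph.n_modules
    ).astype(float)
    module_rates = counts / (n_mod * protocol.t_measure / 1000.0)

    if check_regime:
        if win.n_spikes == 0:
            raise RegimeError(
                f"network died: no spikes in the measurement window "
                f"(S={params.s_intra}, F={params.f_intra}, "
                f"S_ext={params.s_ext}, F_ext={params.f_ext})"
            )
        ceiling = 1000.0 / params.t_refractory
        if module_rates.max() >= 0.98 * ceiling:
            raise RegimeError(
                f"network saturated at the refractory-limited maximum "
                f"({ceiling:.0f} Hz; S={params.s_intra}, F={params.f_intra})"
            )

    # stationarity: first vs second half of the measurement window
    mid = 0.5 * (lo + hi)
    first = np.count_nonzero(win.times < mid)
    second = win.n_spikes - first
    drift = (
        abs(first - second) / max(0.5 * (first + second), 1.0)
        if win.n_spikes
        else 0.0
    )
    if drift > 0.10:
        warnings.warn(
            f"measurement window may be non-stationary "
            f"(half-window rate drift {drift:.1%})",
            RuntimeWarning,
            stacklevel=2,
        )

    traces = {}
    if record_traces:
        traces = {"v": v_trace, "g_exc": ge_trace, "g_inh": gi_trace}
    return SpikingResult(
        spikes=spikes,
        module_rates=module_rates,
        params=params,
        protocol=protocol,
        n_modules=graph.n_modules,
        stationarity_drift=float(drift),
        traces=traces,
    )
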