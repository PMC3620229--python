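"""Deterministic miniature rigs for validating the spiking machinery.

These bypass the Poisson drive (direct conductance clamps or kernel-state
injection) so every run is exactly reproducible and comparable to closed
forms: a single neuron under constant conductances has an analytic firing
period, and a two-neuron relay delivers exactly one alpha kernel whose peak
time and height are known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .rate_network import ParameterError
from .spiking_network import (
    SimulationProtocol,
    SpikingModelParams,
    SynapticGraph,
    run_protocol,
)

__all__ = [
    "FixtureSpec",
    "SingleNeuronRig",
    "RelayResult",
    "make_single_neuron_rig",
    "make_two_neuron_relay",
    "list_fixtures",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Name + size + seed of a fixture; generation is pure."""

    name: str
    size: int = 1
    seed: int = 0


@dataclass(frozen=True)
class SingleNeuronRig:
    """One integrate-and-fire neuron with clamped constant conductances.

    The stepping rules are identical to the network loop, so the rig checks
    the production integrator against the closed-form threshold-crossing
    period of the linear membrane equation.
    """

    g_exc: float
    g_inh: float
    params: SpikingModelParams = SpikingModelParams()

    def run(self, t_total: float = 1000.0, dt: float = 0.05):
        """Simulate; returns (spike times array, final membrane potential)."""
        n_steps = int(round(t_total / dt))
        cap = int(t_total / self.params.t_refractory) + 2
        sp = np.empty(cap)
        n, v = _kernels.run_clamped_neuron(
            self.g_exc,
            self.g_inh,
            dt,
            n_steps,
            self.params.g_leak,
            self.params.v_exc_reversal,
            self.params.v_inh_reversal,
            self.params.t_refractory,
            self.params.v_threshold,
            self.params.v_reset,
            sp,
        )
        return sp[: min(n, cap)].copy(), float(v)

    def firing_rate(self, t_total: float = 1000.0, dt: float = 0.05) -> float:
        """Mean firing rate in Hz over ``t_total``."""
        spikes, _ = self.run(t_total, dt)
        return 1000.0 * spikes.size / t_total


def make_single_neuron_rig(
    g_exc: float, g_inh: float = 0.0, params: SpikingModelParams | None = None
) -> SingleNeuronRig:
    """Minimal rig for the membrane equation under constant conductances."""
    if g_exc < 0 or g_inh < 0:
        raise ParameterError("conductances must be >= 0")
    return SingleNeuronRig(
        g_exc=g_exc, g_inh=g_inh, params=params or SpikingModelParams()
    )


@dataclass(frozen=True)
class RelayResult:
    """Outcome of a relay run: source spike times and the receiver's
    conductance trace."""

    times: np.ndarray  # trace sample times, ms
    receiver_g_exc: np.ndarray
    receiver_v: np.ndarray
    source_spike_times: np.ndarray
    receiver_spike_times: np.ndarray


def make_two_neuron_relay(
    s: float,
    source_delays: tuple[float, ...] = (0.0,),
    params: SpikingModelParams | None = None,
):
    """Relay fixture: one source neuron per entry of ``source_delays``, each
    kicked to spike once at t ~ 0, all projecting onto a single receiver
    with strength ``s`` and the given conduction delay.

    With one source the receiver's excitatory conductance is a single alpha
    kernel: peak ``s/(e*tau_E)`` at one excitatory time constant after the
    (delayed) source spike.  With several sources the trace is the linear
    superposition of the individual kernels.

    Returns a callable running the rig; call with ``t_total`` (ms).
    """
    if s < 0:
        raise ParameterError("strength must be >= 0")
    params = params or SpikingModelParams(delay_min=0.0, delay_max=0.0)
    n_src = len(source_delays)
    n = n_src + 1

    indptr = np.zeros(n + 1, dtype=np.int64)
    indptr[1 : n_src + 1] = np.arange(1, n_src + 1)
    indptr[n_src + 1 :] = n_src
    graph = SynapticGraph(
        indptr=indptr,
        targets=np.full(n_src, n_src, dtype=np.int32),
        strengths=np.full(n_src, float(s)),
        delays=np.asarray(source_delays, dtype=float),
        is_excitatory=np.ones(n, dtype=np.bool_),
        module_of=np.zeros(n, dtype=np.int32),
        n_modules=1,
        geometry=None,
    )

    def run(t_total: float = 30.0) -> RelayResult:
        protocol = SimulationProtocol(
            t_drive=1e-9,
            t_relax=max(t_total - 1e-9, 1e-6) / 2,
            t_measure=max(t_total - 1e-9, 1e-6) / 2,
            poisson_rate=0.0,
        )
        # kick each source with a strong kernel so it crosses threshold fast
        z0 = np.zeros(n)
        z0[:n_src] = 1.0 / params.tau_exc**2  # weight-1 kernel at t = 0
        res = run_protocol(
            params,
            graph,
            protocol=protocol,
            seed=0,
            z_exc_init=z0,
            record_traces=True,
            check_regime=False,
        )
        n_steps = res.traces["v"].shape[0]
        times = np.arange(n_steps) * params.dt
        src = res.spikes.neuron_ids < n_src
        return RelayResult(
            times=times,
            receiver_g_exc=res.traces["g_exc"][:, n_src].copy(),
            receiver_v=res.traces["v"][:, n_src].copy(),
            source_spike_times=res.spikes.times[src],
            receiver_spike_times=res.spikes.times[~src],
        )

    return run


_FIXTURES = {
    "single-neuron-rig": "one neuron, clamped constant conductances "
    "(closed-form firing period oracle)",
    "two-neuron-relay": "source neuron(s) firing once onto a receiver "
    "(alpha-kernel delivery and superposition oracle)",
}


def list_fixtures() -> dict[str, str]:
    """Names and descriptions of the available fixtures."""
    return dict(_FIXTURES)
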