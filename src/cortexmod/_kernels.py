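"""Numba inner loops for the conductance-based integrate-and-fire network.

The temporal update is a modified second-order Runge-Kutta (Heun) scheme:
synaptic kernel states advance exactly over each step (the alpha kernel is
the impulse response of a critically damped linear filter), the membrane
equation takes a Heun step using start- and end-of-step conductances,
threshold crossings are located by linear interpolation inside the step, and
each spike's alpha-kernel contribution reaches its targets after the edge's
conduction delay.  Arrivals inside the current step are applied exactly at
the interpolated arrival time; later arrivals are scheduled on the step grid
through a ring buffer.  Neurons leaving the refractory period mid-step are
integrated over the remaining fraction of the step.
"""

import numpy as np
from numba import njit

__all__ = ["run_network", "run_clamped_neuron"]


@njit(cache=True)
def _heun(v, g_e0, g_i0, g_e1, g_i1, h, g_leak, v_e, v_i):
    """One Heun step of dV/dt = -g_L V - g_E (V - V_E) - g_I (V - V_I)."""
    k1 = -g_leak * v - g_e0 * (v - v_e) - g_i0 * (v - v_i)
    v_pred = v + h * k1
    k2 = -g_leak * v_pred - g_e1 * (v_pred - v_e) - g_i1 * (v_pred - v_i)
    return v + 0.5 * h * (k1 + k2)


@njit(cache=True)
def run_network(
    indptr,
    targets,
    strengths,
    delays,
    is_exc,
    dt,
    n_steps,
    t_drive,
    poisson_rate,
    poisson_amp,
    g_leak,
    v_e,
    v_i,
    tau_e,
    tau_i,
    t_ref,
    v_thresh,
    v_reset,
    seed,
    z_exc_init,
    sp_neuron,
    sp_time,
    record_traces,
    v_trace,
    ge_trace,
    gi_trace,
):
    """Advance the whole network for ``n_steps`` steps of size ``dt`` ms.

    Spikes are written into ``sp_neuron`` / ``sp_time``; returns the spike
    count, -1 if the preallocated spike buffers overflow, -2 on a non-finite
    membrane potential.
    """
    n = indptr.shape[0] - 1
    np.random.seed(seed)

    v = np.full(n, v_reset)
    g_e = np.zeros(n)
    z_e = z_exc_init.copy()
    g_i = np.zeros(n)
    z_i = np.zeros(n)
    g_e0 = np.zeros(n)
    g_i0 = np.zeros(n)
    release = np.full(n, -1.0e9)

    dec_e = np.exp(-dt / tau_e)
    dec_i = np.exp(-dt / tau_i)
    lam = poisson_rate * dt
    inv_tau_e2 = 1.0 / (tau_e * tau_e)
    inv_tau_i2 = 1.0 / (tau_i * tau_i)

    # ring buffer of future kernel-weight arrivals, quantized to step starts
    dmax = 0.0
    for e in range(delays.shape[0]):
        if delays[e] > dmax:
            dmax = delays[e]
    horizon = int(dmax / dt) + 2
    buf_e = np.zeros((horizon, n))
    buf_i = np.zeros((horizon, n))

    step_spikers = np.empty(n, dtype=np.int64)
    step_times = np.empty(n)
    n_spikes = 0
    max_spikes = sp_neuron.shape[0]

    if record_traces:
        for i in range(n):
            v_trace[0, i] = v[i]
            ge_trace[0, i] = g_e[i]
            gi_trace[0, i] = g_i[i]

    for step in range(n_steps):
        t0 = step * dt
        t1 = t0 + dt
        slot = step % horizon

        # scheduled arrivals for this step (impulses at the step start)
        for i in range(n):
            if buf_e[slot, i] != 0.0:
                z_e[i] += buf_e[slot, i] * inv_tau_e2
                buf_e[slot, i] = 0.0
            if buf_i[slot, i] != 0.0:
                z_i[i] += buf_i[slot, i] * inv_tau_i2
                buf_i[slot, i] = 0.0

        # external Poisson drive: events pooled at the step start
        if t0 < t_drive and poisson_rate > 0.0:
            for i in range(n):
                k = np.random.poisson(lam)
                if k > 0:
                    z_e[i] += k * poisson_amp * inv_tau_e2

        # exact propagation of the alpha-kernel filter states over dt
        for i in range(n):
            g_e0[i] = g_e[i]
            g_i0[i] = g_i[i]
            g_e[i] = dec_e * (g_e[i] + dt * z_e[i])
            z_e[i] = dec_e * z_e[i]
            g_i[i] = dec_i * (g_i[i] + dt * z_i[i])
            z_i[i] = dec_i * z_i[i]

        # membrane update with threshold interpolation
        n_step_spikes = 0
        for i in range(n):
            rel = release[i]
            if t0 < rel:
                if rel >= t1:
                    v[i] = v_reset
                    continue
                h = t1 - rel
                frac = (rel - t0) / dt
                ge_a = g_e0[i] + (g_e[i] - g_e0[i]) * frac
                gi_a = g_i0[i] + (g_i[i] - g_i0[i]) * frac
                v_start = v_reset
                t_start = rel
            else:
                h = dt
                ge_a = g_e0[i]
                gi_a = g_i0[i]
                v_start = v[i]
                t_start = t0
            v_new = _heun(
                v_start, ge_a, gi_a, g_e[i], g_i[i], h, g_leak, v_e, v_i
            )
            if v_new >= v_thresh and v_new > v_start:
                t_s = t_start + h * (v_thresh - v_start) / (v_new - v_start)
                if t_s > t1:
                    t_s = t1
                step_spikers[n_step_spikes] = i
                step_times[n_step_spikes] = t_s
                n_step_spikes += 1
                release[i] = t_s + t_ref
                v[i] = v_reset
            else:
                v[i] = v_new
            if not np.isfinite(v[i]):
                return -2

        # deliver this step's spikes: within-step arrivals exactly at the
        # interpolated arrival time, later ones via the ring buffer
        for s in range(n_step_spikes):
            i = step_spikers[s]
            t_s = step_times[s]
            if n_spikes >= max_spikes:
                return -1
            sp_neuron[n_spikes] = i
            sp_time[n_spikes] = t_s
            n_spikes += 1
            exc = is_exc[i]
            for e in range(indptr[i], indptr[i + 1]):
                j = targets[e]
                w = strengths[e]
                arr = t_s + delays[e]
                if arr < t1:
                    rem = t1 - arr
                    if exc:
                        decay = np.exp(-rem / tau_e)
                        z_e[j] += w * decay * inv_tau_e2
                        g_e[j] += w * decay * rem * inv_tau_e2
                    else:
                        decay = np.exp(-rem / tau_i)
                        z_i[j] += w * decay * inv_tau_i2
                        g_i[j] += w * decay * rem * inv_tau_i2
                else:
                    aslot = int(arr / dt + 0.5) % horizon
                    if exc:
                        buf_e[aslot, j] += w
                    else:
                        buf_i[aslot, j] += w

        if record_traces:
            for i in range(n):
                v_trace[step + 1, i] = v[i]
                ge_trace[step + 1, i] = g_e[i]
                gi_trace[step + 1, i] = g_i[i]

    return n_spikes


@njit(cache=True)
def run_clamped_neuron(
    g_e,
    g_i,
    dt,
    n_steps,
    g_leak,
    v_e,
    v_i,
    t_ref,
    v_thresh,
    v_reset,
    sp_time,
):
    """Single neuron with conductances clamped constant: same stepping rules
    as the network loop (Heun, interpolated crossings, partial-step release).

    Returns (number of spikes, final membrane potential).
    """
    v = v_reset
    release = -1.0e9
    n_spikes = 0
    max_spikes = sp_time.shape[0]
    for step in range(n_steps):
        t0 = step * dt
        t1 = t0 + dt
        if t0 < release:
            if release >= t1:
                v = v_reset
                continue
            h = t1 - release
            v_start = v_reset
            t_start = release
        else:
            h = dt
            v_start = v
            t_start = t0
        v_new = _heun(v_start, g_e, g_i, g_e, g_i, h, g_leak, v_e, v_i)
        if v_new >= v_thresh and v_new > v_start:
            t_s = t_start + h * (v_thresh - v_start) / (v_new - v_start)
            if n_spikes < max_spikes:
                sp_time[n_spikes] = t_s
            n_spikes += 1
            release = t_s + t_ref
            v = v_reset
        else:
            v = v_new
    return n_spikes, v
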