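import numpy as np
import pytest

from cortexmod import SpikingModelParams, build_synaptic_graph
from cortexmod import experiments as ex


def small_module_params(n: int = 300, f: float = 0.3, **kwargs) -> SpikingModelParams:
    """Small self-sustaining module: coupling strength derived so the
    per-module total coupling K = N*F*S matches the reference configuration."""
    n_exc = int(round(0.8 * n))
    defaults = dict(
        n_excitatory=n_exc,
        n_inhibitory=n - n_exc,
        f_intra=f,
        s_intra=ex.scaled_coupling_strength(n, f),
    )
    defaults.update(kwargs)
    return SpikingModelParams(**defaults)


@pytest.fixture(scope="session")
def small_graph():
    """300-neuron single module used by several dynamics tests."""
    params = small_module_params()
    return params, build_synaptic_graph(params, 1, seed=42)


def analytic_if_rate(g_e, g_i=0.0, g_leak=0.05, v_e=14.0 / 3.0,
                     v_i=-2.0 / 3.0, v_thresh=1.0, t_ref=5.0):
    """Closed-form firing rate (Hz) of the membrane equation under constant
    conductances: independent threshold-crossing oracle.

    dV/dt = -g_L V - g_E (V - V_E) - g_I (V - V_I) has fixed point
    V_inf = (g_E V_E + g_I V_I) / (g_L + g_E + g_I) approached with time
    constant tau_eff = 1 / (g_L + g_E + g_I); if V_inf > threshold the
    period is tau_eff * ln(V_inf / (V_inf - V_T)) + t_ref.
    """
    g_tot = g_leak + g_e + g_i
    tau_eff = 1.0 / g_tot
    v_inf = (g_e * v_e + g_i * v_i) * tau_eff
    if v_inf <= v_thresh:
        return 0.0
    period = tau_eff * np.log(v_inf / (v_inf - v_thresh)) + t_ref
    return 1000.0 / period
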