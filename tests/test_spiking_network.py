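"""Unit and property tests for the conductance-based integrate-and-fire model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from cortexmod import (
    ParameterError,
    RegimeError,
    SimulationProtocol,
    SpikingModelParams,
    alpha_kernel,
    build_synaptic_graph,
    delete_edges,
    run_protocol,
    scale_inter_strength,
)
from cortexmod.fixtures import make_single_neuron_rig

from conftest import analytic_if_rate, small_module_params


class TestAlphaKernel:
    def test_vanishes_at_onset_and_before(self):
        assert alpha_kernel(0.0, 1.0) == 0.0
        assert alpha_kernel(-3.0, 1.0) == 0.0

    @pytest.mark.parametrize("tau", [1.0, 5.0 / 3.0])
    def test_unit_time_integral(self, tau):
        integral, err = quad(lambda t: alpha_kernel(t, tau), 0, 80)
        assert integral == pytest.approx(1.0, abs=max(1e-8, 10 * err))

    @pytest.mark.parametrize("tau", [1.0, 5.0 / 3.0])
    def test_peak_at_tau(self, tau):
        t = np.linspace(0, 12, 240001)
        k = alpha_kernel(t, tau)
        assert t[np.argmax(k)] == pytest.approx(tau, abs=1e-3)
        assert k.max() == pytest.approx(1.0 / (np.e * tau), rel=1e-6)

    def test_invalid_tau(self):
        with pytest.raises(ParameterError):
            alpha_kernel(1.0, 0.0)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(t=st.floats(-10.0, 200.0), tau=st.floats(0.1, 10.0))
    def test_nonnegative_and_below_peak_everywhere(self, t, tau):
        v = alpha_kernel(t, tau)
        assert v >= 0.0
        assert v <= 1.0 / (np.e * tau) + 1e-12


class TestSynapticGraph:
    def test_in_degree_matches_binomial(self):
        """N=900, F=0.2: the mean in-degree sits within 4 standard errors
        of the Binomial(900, 0.2) expectation of 180."""
        params = SpikingModelParams(
            n_excitatory=720, n_inhibitory=180, f_intra=0.2, s_intra=0.0085
        )
        g = build_synaptic_graph(params, 1, seed=11)
        deg = g.in_degree()
        se_mean = np.sqrt(900 * 0.2 * 0.8) / np.sqrt(900)
        assert abs(deg.mean() - 180.0) < 4 * se_mean
        assert deg.std() == pytest.approx(np.sqrt(900 * 0.2 * 0.8), rel=0.15)

    def test_zero_fraction_gives_empty_graph(self):
        params = SpikingModelParams(
            n_excitatory=40, n_inhibitory=10, f_intra=0.0
        )
        assert build_synaptic_graph(params, 1, seed=0).n_edges == 0

    def test_full_fraction_gives_complete_graph(self):
        """F=1 connects every ordered pair, self-edges included."""
        params = SpikingModelParams(
            n_excitatory=80, n_inhibitory=20, f_intra=1.0
        )
        assert build_synaptic_graph(params, 1, seed=0).n_edges == 100 * 100

    def test_strengths_and_kernel_classes(self):
        params = SpikingModelParams(
            n_excitatory=16, n_inhibitory=4, f_intra=0.5,
            s_intra=0.002, s_ext=0.001, f_ext=0.5,
        )
        g = build_synaptic_graph(params, 2, seed=1)
        inter = g.edge_is_inter()
        assert np.all(g.strengths[~inter] == 0.002)
        assert np.all(g.strengths[inter] == 0.001)
        # kernel class comes from the presynaptic neuron's type
        for pre, post, s, kind in g.adjacency():
            expected = "excitatory" if g.is_excitatory[pre] else "inhibitory"
            assert kind == expected

    def test_inter_excitatory_only_flag(self):
        params = SpikingModelParams(
            n_excitatory=40, n_inhibitory=10, f_intra=0.2,
            s_ext=0.001, f_ext=0.2,
        )
        g = build_synaptic_graph(params, 2, seed=2, inter_excitatory_only=True)
        pre = np.repeat(np.arange(g.n_neurons), np.diff(g.indptr))
        inter = g.edge_is_inter()
        assert np.all(g.is_excitatory[pre[inter]])

    def test_geometry_recorded_and_validated(self):
        params = SpikingModelParams(n_excitatory=80, n_inhibitory=19)
        with pytest.raises(ParameterError):
            build_synaptic_graph(params, 1, geometry=(10, 10), seed=0)
        params = SpikingModelParams(n_excitatory=80, n_inhibitory=20)
        g = build_synaptic_graph(params, 1, geometry=(10, 10), seed=0)
        assert g.geometry == (10, 10)

    def test_determinism(self):
        params = SpikingModelParams(n_excitatory=40, n_inhibitory=10)
        a = build_synaptic_graph(params, 2, seed=5)
        b = build_synaptic_graph(params, 2, seed=5)
        np.testing.assert_array_equal(a.targets, b.targets)
        np.testing.assert_array_equal(a.delays, b.delays)


class TestEdgeEditing:
    @pytest.fixture(scope="class")
    def two_module_graph(self):
        params = SpikingModelParams(
            n_excitatory=160, n_inhibitory=40, f_intra=0.3,
            s_intra=0.002, s_ext=0.002, f_ext=0.3,
        )
        return build_synaptic_graph(params, 2, seed=3)

    def test_random_deletion_hits_expected_fraction(self, two_module_graph):
        g = two_module_graph
        n_inter = int(g.edge_is_inter().sum())
        g2 = delete_edges(g, 0.24, seed=1, which="inter")
        removed = g.n_edges - g2.n_edges
        sd = np.sqrt(n_inter * 0.24 * 0.76)
        assert abs(removed - 0.24 * n_inter) < 5 * sd
        # intra edges untouched
        assert (~g2.edge_is_inter()).sum() == (~g.edge_is_inter()).sum()

    def test_exact_deletion_count(self, two_module_graph):
        g = two_module_graph
        n_inter = int(g.edge_is_inter().sum())
        g2 = delete_edges(g, 0.5, seed=1, which="inter", exact=True)
        assert g.n_edges - g2.n_edges == round(0.5 * n_inter)

    def test_full_deletion_disconnects_modules(self, two_module_graph):
        g2 = delete_edges(two_module_graph, 1.0, seed=0, which="inter")
        assert g2.edge_is_inter().sum() == 0

    def test_strength_scaling_targets_inter_edges_only(self, two_module_graph):
        g = two_module_graph
        g2 = scale_inter_strength(g, 0.5)
        inter = g2.edge_is_inter()
        assert np.all(g2.strengths[inter] == 0.001)
        assert np.all(g2.strengths[~inter] == 0.002)

    def test_invalid_fraction(self, two_module_graph):
        with pytest.raises(ParameterError):
            delete_edges(two_module_graph, 1.5)


class TestSingleNeuronDynamics:
    @pytest.mark.parametrize("g_e,g_i", [(0.02, 0.0), (0.03, 0.0),
                                         (0.05, 0.01), (0.02, 0.003)])
    def test_firing_rate_matches_closed_form(self, g_e, g_i):
        """Constant-conductance firing rates match the analytic
        threshold-crossing period within 1% at dt = 0.05 ms."""
        rig = make_single_neuron_rig(g_e, g_i)
        spikes, _ = rig.run(t_total=2000.0, dt=0.05)
        assert spikes.size > 10
        rate = 1000.0 / np.diff(spikes).mean()
        assert rate == pytest.approx(analytic_if_rate(g_e, g_i), rel=0.01)

    def test_subthreshold_fixed_point(self):
        """G_E = 0.01 keeps V_inf = 0.01*(14/3)/0.06 < 1: no spikes and V
        converges to the analytic fixed point."""
        rig = make_single_neuron_rig(0.01)
        spikes, v = rig.run(t_total=1000.0, dt=0.05)
        assert spikes.size == 0
        assert v == pytest.approx(0.01 * (14 / 3) / 0.06, abs=1e-6)

    def test_no_input_stays_at_rest(self):
        spikes, v = make_single_neuron_rig(0.0).run(t_total=200.0)
        assert spikes.size == 0
        assert v == 0.0


class TestNetworkDynamics:
    @pytest.fixture(scope="class")
    def small_run(self, small_graph):
        params, graph = small_graph
        return params, graph, run_protocol(params, graph, seed=0)

    def test_self_sustained_rate_is_stable(self, small_run):
        """After drive removal the module settles into a steady
        self-sustained state (drift between window halves < 10%)."""
        _, _, res = small_run
        assert res.module_rates[0] > 20.0
        assert res.stationarity_drift < 0.10

    def test_refractoriness_bounds_isi(self, small_run):
        _, _, res = small_run
        assert res.spikes.isi_minimum() >= res.params.t_refractory - 1e-9

    def test_spike_times_inside_simulation(self, small_run):
        _, _, res = small_run
        assert res.spikes.times.min() >= 0.0
        assert res.spikes.times.max() <= res.protocol.t_total + 1e-9

    def test_seed_determinism(self, small_graph):
        params, graph = small_graph
        a = run_protocol(params, graph, seed=3)
        b = run_protocol(params, graph, seed=3)
        np.testing.assert_array_equal(a.spikes.times, b.spikes.times)
        np.testing.assert_array_equal(a.spikes.neuron_ids, b.spikes.neuron_ids)

    def test_voltage_and_conductance_bounds(self):
        """V stays between the reversal potentials; conductances stay
        non-negative (recorded at every step of a small run)."""
        params = small_module_params(n=120)
        graph = build_synaptic_graph(params, 1, seed=8)
        proto = SimulationProtocol(t_drive=100.0, t_relax=60.0, t_measure=60.0)
        res = run_protocol(
            params, graph, protocol=proto, seed=1,
            record_traces=True, check_regime=False,
        )
        v = res.traces["v"]
        assert v.max() <= params.v_exc_reversal + 1e-9
        assert v.min() >= params.v_inh_reversal - 1e-9
        assert res.traces["g_exc"].min() >= 0.0
        assert res.traces["g_inh"].min() >= 0.0

    def test_step_size_convergence(self, small_graph):
        """Halving dt changes the measured mean rate by < 2%."""
        params, _ = small_graph
        rates = {}
        for dt in (0.1, 0.05):
            p = params.replace(dt=dt)
            g = build_synaptic_graph(p, 1, seed=42)
            rates[dt] = run_protocol(p, g, seed=0).module_rates[0]
        assert abs(rates[0.05] - rates[0.1]) / rates[0.1] < 0.02

    def test_dead_network_raises_regime_error(self):
        """Without recurrent coupling the network falls silent after the
        drive is removed and the run is rejected."""
        params = small_module_params(n=100, s_intra=0.0)
        graph = build_synaptic_graph(params, 1, seed=0)
        with pytest.raises(RegimeError, match="died"):
            run_protocol(params, graph, seed=0)

    def test_saturated_network_raises_regime_error(self):
        """Excessive coupling drives every neuron at the refractory-limited
        ceiling and the run is rejected."""
        params = small_module_params(n=100, s_intra=1.0)
        graph = build_synaptic_graph(params, 1, seed=0)
        with pytest.raises(RegimeError, match="saturated"):
            run_protocol(params, graph, seed=0)

    def test_zero_delay_state_collapses(self):
        """With strictly zero conduction delay the asynchronous state is
        unstable: the network synchronizes and dies once the drive stops."""
        params = small_module_params(n=300, delay_min=0.0, delay_max=0.0)
        graph = build_synaptic_graph(params, 1, seed=42)
        with pytest.raises(RegimeError, match="died"):
            run_protocol(params, graph, seed=0)

    def test_rate_insensitive_to_drive_settings(self, small_graph):
        """The drive only initializes the self-sustained attractor: +-50%
        changes in Poisson rate or amplitude move the measured activity by
        less than 3%."""
        params, graph = small_graph
        base = run_protocol(params, graph, seed=0).module_rates[0]
        for rate, amp in [(0.25, 0.06), (0.75, 0.06), (0.5, 0.03), (0.5, 0.09)]:
            proto = SimulationProtocol(poisson_rate=rate, poisson_amplitude=amp)
            r = run_protocol(params, graph, protocol=proto, seed=0).module_rates[0]
            assert abs(r - base) / base < 0.03

    def test_rate_tracks_total_coupling(self):
        """The self-sustained rate increases with the per-module total
        coupling K = N*F*S."""
        rates = []
        for k_scale in (1.0, 2.0):
            params = small_module_params(n=300)
            params = params.replace(s_intra=params.s_intra * k_scale)
            graph = build_synaptic_graph(params, 1, seed=13)
            rates.append(run_protocol(params, graph, seed=0).module_rates[0])
        assert rates[1] > rates[0] * 1.2


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(v_threshold=-1.0),
            dict(v_inh_reversal=0.5),
            dict(f_intra=1.2),
            dict(f_ext=-0.1),
            dict(s_intra=-1e-3),
            dict(tau_exc=0.0),
            dict(g_leak=0.0),
            dict(delay_min=2.0, delay_max=1.0),
        ],
    )
    def test_invariant_violations(self, kwargs):
        with pytest.raises(ParameterError):
            SpikingModelParams(**kwargs)

    def test_protocol_validation(self):
        with pytest.raises(ParameterError):
            SimulationProtocol(t_drive=0.0)
        with pytest.raises(ParameterError):
            SimulationProtocol(poisson_rate=-1.0)

    def test_default_excitatory_fraction(self):
        p = SpikingModelParams()
        assert p.n_excitatory / p.n_total == pytest.approx(0.8)
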