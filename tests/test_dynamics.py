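"""Admissible ODE models: thresholds, stimuli, integration invariants."""

import numpy as np
import pytest

from fibersync import (NeuronNetwork, build_stimulus, integrate,
                       minimal_balanced_coloring, rhs, threshold_voltage)
from fibersync.dynamics import (MV_PER_V, ConfigurationError, DivergenceError,
                                ModelParams)
from fibersync.synthetic_data import fixture


@pytest.fixture
def isolated():
    net = NeuronNetwork()
    net.add_node("A")
    return net


class TestModelParams:
    def test_s_eq_identity(self, params):
        assert params.s_eq == pytest.approx(
            params.a_r / (params.a_r + 2 * params.a_d))
        assert round(params.s_eq, 2) == 0.09

    def test_gamma_formula_close_to_adopted_value(self, params):
        formula = ModelParams.gamma_from_sigmoid_range(36.0)
        assert formula == pytest.approx(122.07, abs=0.01)
        assert abs(params.gamma - formula) < 3.0

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(alpha_leak=0.0)


class TestThresholdVoltage:
    def test_isolated_neuron_rests_without_drive(self, isolated, params):
        for model in ("gap", "chem1", "chem2"):
            vth = threshold_voltage(isolated, params, model, 0.0)
            assert vth[0] == pytest.approx(params.V_rest)

    def test_isolated_neuron_closed_form(self, isolated, params):
        I = 0.25
        vth = threshold_voltage(isolated, params, "chem1", I)
        expected = params.V_rest + MV_PER_V * params.alpha_ext * I \
            / params.alpha_leak
        assert vth[0] == pytest.approx(expected)

    @pytest.mark.parametrize("model", ["chem1", "chem2", "gap"])
    def test_rhs_residual_vanishes_at_threshold(self, model, params):
        name = "gap_like" if model == "gap" else "backward_chem_like"
        net, _ = fixture(name, seed=1)
        drive = {n: 0.4 for n in list(net.nodes)[:2]}
        vth = threshold_voltage(net, params, model, drive)
        state = vth if model != "chem2" else np.concatenate(
            [vth, np.full(net.n, params.s_eq)])
        stim = build_stimulus(None, list(drive), I_drive=0.4)
        d = rhs(model, state, 0.0, net, params, stim, V_threshold=vth)
        assert np.abs(d).max() < 1e-10


class TestRhs:
    def test_isolated_neuron_at_rest_has_zero_derivative(self, isolated,
                                                         params):
        for model in ("gap", "chem1"):
            v = np.array([params.V_rest])
            d = rhs(model, v, 0.0, isolated, params,
                    V_threshold=np.array([params.V_rest]))
            assert d[0] == pytest.approx(0.0)

    def test_equal_voltages_reduce_gap_to_leak(self, params):
        net = NeuronNetwork(directed=False)
        net.add_edge("a", "b", 1)
        v = np.array([-30.0, -30.0])
        d = rhs("gap", v, 0.0, net, params, V_threshold=v)
        leak = -params.alpha_leak * (v - params.V_rest)
        assert d == pytest.approx(leak)

    def test_gap_model_rejects_directed_edge_set(self, params):
        net = NeuronNetwork()
        net.add_edge("a", "b", 1)
        with pytest.raises(ConfigurationError):
            rhs("gap", np.zeros(2), 0.0, net, params,
                V_threshold=np.zeros(2))


class TestStimulus:
    def test_constant_when_no_oscillation_or_noise(self):
        st = build_stimulus(None, ["a"], I_drive=1.2)
        assert st.deterministic(0.0) == st.deterministic(0.33) == 1.2

    def test_two_frequency_channels_are_distinct(self):
        inter = build_stimulus(None, ["i"], I_osc=1.0, f=2.0)
        motor = build_stimulus(None, ["m"], I_osc=1.0, f=1.0)
        t = 0.125
        assert inter.deterministic(t) != motor.deterministic(t)

    def test_partial_fiber_targeting_warns(self):
        net, part = fixture("forward_chem_like", seed=0)
        pair = [c for c in part.cells if len(c) == 2][0]
        with pytest.warns(UserWarning, match="part of fiber"):
            build_stimulus(part, pair[:1], I_drive=1.0)

    def test_noise_walk_stays_in_scale(self, params):
        net, part = fixture("two_regulator_hub")
        st = build_stimulus(part, ["S1", "S2"], noise_scale=0.1,
                            shared_across_fiber=False)
        res = integrate("chem1", net, params, st, T=0.2, dt=1e-3, seed=4)
        noise = res.stim_record[:, res.nodes.index("S1")]
        assert noise.max() <= 0.1 + 1e-12
        assert noise.min() >= -0.1 - 1e-12
        assert noise.max() - noise.min() > 0.05  # walk actually moves

    def test_max_amplitude_bookkeeping(self):
        st = build_stimulus(None, ["x"], I_drive=0.1, I_osc=0.5,
                            noise_scale=0.01)
        assert st.max_amplitude == pytest.approx(0.61)


class TestIntegrate:
    def test_gap_network_settles_to_global_rest(self, params):
        net, _ = fixture("gap_like", seed=0)
        rng = np.random.default_rng(0)
        v0 = params.V_rest + rng.normal(0, 2.0, net.n)
        res = integrate("gap", net, params, None, initial_state=v0,
                        T=1.0, dt=1e-3)
        assert np.abs(res.V[-1] - params.V_rest).max() < 1e-3
        assert res.V[-1].std() < 1e-10

    @pytest.mark.parametrize("model", ["chem1", "chem2"])
    def test_fiber_symmetric_states_stay_synchronous(self, model, params):
        net, part = fixture("forward_chem_like", seed=1)
        rng = np.random.default_rng(2)
        cell_v = {c: params.V_rest + rng.normal(0, 2)
                  for c in part.cell_ids}
        v0 = np.array([cell_v[part.cell_of(u)] for u in net.nodes])
        y0 = v0 if model == "chem1" else np.concatenate(
            [v0, np.full(net.n, params.s_eq)])
        pair = [c for c in part.cells if len(c) == 2][0]
        stim = build_stimulus(part, pair, I_drive=0.3, I_osc=0.1, f=2.0)
        res = integrate(model, net, params, stim, initial_state=y0,
                        T=1.0, dt=1e-3)
        for cell in part.cells:
            cols = [res.nodes.index(u) for u in cell]
            spread = np.abs(res.V[:, cols] -
                            res.V[:, cols[0]][:, None]).max()
            assert spread < 1e-10

    def test_chem2_synaptic_variable_bounded(self, params):
        net, _ = fixture("backward_chem_like", seed=0)
        rng = np.random.default_rng(1)
        y0 = np.concatenate([
            params.V_rest + rng.normal(0, 5, net.n),
            rng.uniform(0, 1, net.n)])
        res = integrate("chem2", net, params, None, initial_state=y0,
                        T=0.5, dt=1e-3)
        assert res.s.min() >= -1e-12
        assert res.s.max() <= 1.0 + 1e-12

    def test_rk4_fourth_order_convergence(self, params):
        net, _ = fixture("two_regulator_hub")
        y0 = np.array([-30.0, -40.0, -35.0])

        def terminal(dt):
            return integrate("chem1", net, params, None, initial_state=y0,
                             T=0.08, dt=dt).V[-1]

        ref = terminal(5e-4)
        err_coarse = np.abs(terminal(8e-3) - ref).max()
        err_fine = np.abs(terminal(4e-3) - ref).max()
        assert err_coarse / err_fine > 10  # ~16 for order 4

    def test_deterministic_runs_permutation_equivariant(self, params):
        net, _ = fixture("multilayer_pair", seed=0)
        relabel = {u: f"zz_{u}" for u in net.nodes}
        twin = NeuronNetwork()
        for u in net.nodes:
            twin.add_node(relabel[u])
        for u, v, w in net.edges():
            twin.add_edge(relabel[u], relabel[v], w)
        rng = np.random.default_rng(3)
        v0 = {u: params.V_rest + rng.normal(0, 1) for u in net.nodes}
        res_a = integrate("chem1", net, params, None,
                          initial_state=np.array([v0[u] for u in net.nodes]),
                          T=0.3, dt=1e-3)
        res_b = integrate(
            "chem1", twin, params, None,
            initial_state=np.array([v0[u[3:]] for u in twin.nodes]),
            T=0.3, dt=1e-3)
        for u in net.nodes:
            np.testing.assert_array_equal(res_a.voltage(u),
                                          res_b.voltage(f"zz_{u}"))

    def test_divergence_reports_first_bad_step(self, params):
        net = NeuronNetwork()
        net.add_node("A")
        bad = ModelParams()
        with pytest.raises(DivergenceError):
            integrate("chem1", net, bad, None,
                      initial_state=np.array([np.inf]), T=0.01, dt=1e-3)

    def test_fixed_seed_reproducible(self, params):
        net, part = fixture("two_regulator_hub")
        st = build_stimulus(part, ["S1", "S2"], I_drive=0.1,
                            noise_scale=0.05, shared_across_fiber=False)
        a = integrate("chem1", net, params, st, T=0.1, dt=1e-3, seed=9)
        b = integrate("chem1", net, params, st, T=0.1, dt=1e-3, seed=9)
        np.testing.assert_array_equal(a.V, b.V)
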