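"""Core simulator: determinism, refractoriness, rate statistics,
single-synapse integration, preparatory-phase protocol."""

import math

import numpy as np
import pytest
from scipy import stats

import stospike as sp
from stospike.network import (InputProcess, NetworkModel, NeuronParams,
                              SynapseParams)
from stospike.simulate import prepare_initial_state, run


class TestDeterminism:
    def test_same_seed_identical_record(self, rect_pair):
        a = run(rect_pair, 3000.0, dt=0.5, seed=9).spikes
        b = run(rect_pair, 3000.0, dt=0.5, seed=9).spikes
        assert a == b

    def test_different_seed_differs(self, rect_pair):
        a = run(rect_pair, 5000.0, dt=0.5, seed=9).spikes
        b = run(rect_pair, 5000.0, dt=0.5, seed=10).spikes
        assert a != b

    def test_zero_rate_network_is_silent(self):
        # hazard_base_rate must be > 0, so "rate zero" means a threshold
        # far above reach with a tiny cap
        p = NeuronParams(hazard_threshold=300.0, rate_cap=0.011)
        net = NetworkModel(neurons=[p], synapses=[])
        rec = run(net, 2000.0, dt=0.5, seed=0).spikes
        assert len(rec) == 0


class TestRefractorinessAndRates:
    def test_refractory_enforced(self, single_hot_neuron):
        rec = run(single_hot_neuron, 20000.0, dt=0.5, seed=2).spikes
        assert rec.check_refractory(single_hot_neuron)
        isis = np.diff(rec.spikes_of(0))
        assert isis.min() >= 2.0 - 1e-9

    def test_spike_probability_bounded_by_cap(self, single_hot_neuron):
        # empirical per-step spike frequency never exceeds
        # 1 - exp(-r_max dt) + 3 sigma
        dt = 0.5
        rec = run(single_hot_neuron, 50000.0, dt=dt, seed=3).spikes
        n_steps = int(50000 / dt)
        p_cap = 1 - math.exp(-0.2 * dt)
        phat = len(rec) / n_steps
        sigma = math.sqrt(p_cap * (1 - p_cap) / n_steps)
        assert phat <= p_cap + 3 * sigma

    def test_clamped_neuron_is_poisson_with_dead_time(self):
        # shifted-exponential ISI distribution (KS test at alpha = 0.01)
        p = NeuronParams(hazard_threshold=-66.0, bias_potential=10.0,
                         refractory_abs=2.0, rate_cap=1.0)
        net = NetworkModel(neurons=[p], synapses=[])
        dt = 0.1
        dur = 60000.0   # ~8500 intervals at ~117 Hz
        rec = run(net, dur, dt=dt, seed=11).spikes
        isis = np.diff(rec.spikes_of(0))
        assert isis.size > 5000
        isis = isis[:5000]
        # V - V_T = E_L + bias - V_T = 6 mV; rate = r0 * e^(6/2)
        rate = 0.01 * math.exp(3.0)
        p_step = 1 - math.exp(-rate * dt)
        # discrete-time dead-time process: ISI = refractory + m*dt with
        # m geometric (m >= 0 failures before a success); exact KS
        # statistic against that CDF
        shifted = np.round((isis - 2.0) / dt).astype(int)
        assert shifted.min() >= 0
        ks = 0.0
        for k in np.unique(shifted):
            emp = np.mean(shifted <= k)
            theo = 1 - (1 - p_step) ** (k + 1)
            ks = max(ks, abs(emp - theo))
        crit = stats.ksone.ppf(1 - 0.005, 5000)
        assert ks < crit

    def test_poisson_count_within_tolerance(self, single_hot_neuron):
        # expected count ~ L / (refr + dt/p) for Poisson with dead time
        dur, dt = 60000.0, 0.1
        rec = run(single_hot_neuron, dur, dt=dt, seed=5).spikes
        r = 0.2  # capped rate, 1/ms
        expect = dur / (2.0 + dt / (1 - math.exp(-r * dt)))
        assert abs(len(rec) - expect) <= 4 * math.sqrt(expect)


class TestSynapticIntegration:
    def test_resting_network_stays_at_rest(self):
        p = NeuronParams()
        net = NetworkModel(neurons=[p], synapses=[])
        res = run(net, 10.0, dt=0.1, seed=0, record="spikes+potentials",
                  random_init=False)
        assert np.allclose(res.potentials[:, 0], p.resting_potential)

    def test_single_conductance_delivery_matches_closed_form(self):
        # one forced presynaptic input spike onto a passive membrane:
        # exponential-Euler update with decaying conductance
        pre = NeuronParams(refractory_abs=0.0)
        post = NeuronParams()
        syn = SynapseParams(pre=0, post=1, weight=5.0, delay=1.0,
                            kind="conductance-exp")
        net = NetworkModel(
            neurons=[pre, post], synapses=[syn],
            inputs=[InputProcess(neuron_ids=(0,), kind="schedule",
                                 schedule=((0.0, 100.0), (0.05, 0.0)))],
            input_neuron_ids=(0,))
        dt, tau_e = 0.1, 5.0
        res = run(net, 6.0, dt=dt, seed=1, record="spikes+potentials",
                  random_init=False, tau_e=tau_e)
        ts = res.spikes.spikes_of(0)
        assert ts.size == 1   # the scheduled pulse guarantees one spike
        t_spk = ts[0]
        # replicate the discrete update independently
        gL, C, EL, Ee = 10.0, 200.0, -70.0, 0.0
        V, g = EL, 0.0
        Vs = []
        k_deliver = int(round(t_spk / dt)) + int(round(syn.delay / dt)) - 1
        for k in range(int(round(6.0 / dt))):
            if k == k_deliver:
                g += syn.weight
            g_tot = gL + g
            V_inf = (gL * EL + g * Ee) / g_tot
            V = V_inf + (V - V_inf) * math.exp(-dt * g_tot / C)
            g *= math.exp(-dt / tau_e)
            Vs.append(V)
        assert np.allclose(res.potentials[k_deliver + 1:, 1],
                           Vs[k_deliver:-1], atol=1e-9)

    def test_dt_too_large_for_delay_rejected(self, rect_pair):
        with pytest.raises(ValueError):
            run(rect_pair, 100.0, dt=2.0, seed=0)

    def test_dt_robustness_of_firing_rate(self):
        # halving dt changes the mean rate of a reference 2-neuron
        # excitatory loop by < 5%
        neurons = [NeuronParams(hazard_threshold=-65.0, refractory_abs=5.0,
                                rate_cap=0.5),
                   NeuronParams(hazard_threshold=-65.0, refractory_abs=5.0,
                                rate_cap=0.5)]
        synapses = [SynapseParams(pre=0, post=1, weight=4.0, delay=1.0,
                                  kind="current-rect", pulse_length=10.0),
                    SynapseParams(pre=1, post=0, weight=4.0, delay=1.0,
                                  kind="current-rect", pulse_length=10.0)]
        net = NetworkModel(neurons=neurons, synapses=synapses)
        dur = 300000.0
        r1 = len(run(net, dur, dt=1.0, seed=7).spikes)
        r2 = len(run(net, dur, dt=0.5, seed=7).spikes)
        assert abs(r1 - r2) / max(r1, r2) < 0.05


class TestSingleStep:
    def test_step_advances_clock_and_matches_run(self, rect_pair):
        from stospike.simulate import _compiled, _fresh_state, step
        import numpy as np
        cn = _compiled(rect_pair, 0.5)
        st = _fresh_state(cn, np.random.default_rng(5))
        ids = []
        for _ in range(2000):
            spiked = step(st, rect_pair, 0.5)
            ids.extend((int(i), st.clock) for i in spiked)
        assert st.clock == pytest.approx(1000.0)
        ref = run(rect_pair, 1000.0, dt=0.5, seed=5).spikes
        assert [i for i, _ in ids] == ref.neuron_ids.tolist()


class TestInputProcesses:
    def test_markov_modulated_rates_switch(self):
        # two-state modulator alternating high/low rate every 500 ms;
        # spike counts in the two dwell classes must differ strongly
        p = NeuronParams(refractory_abs=0.0)
        net = NetworkModel(
            neurons=[p],
            inputs=[InputProcess(
                neuron_ids=(0,), kind="markov-modulated",
                modulator={"rates": [0.2, 0.001],
                           "transition": [[0.0, 1.0], [1.0, 0.0]],
                           "dwell": 500.0})],
            synapses=[], input_neuron_ids=(0,))
        rec = run(net, 8000.0, dt=0.5, seed=13).spikes
        # deterministic alternation: dwell k has rate 0.2 for even k
        even = np.sum((rec.times // 500).astype(int) % 2 == 0)
        odd = len(rec) - even
        assert even > 10 * max(odd, 1)

    def test_periodic_rate_function(self):
        p = NeuronParams(refractory_abs=0.0)
        net = NetworkModel(
            neurons=[p],
            inputs=[InputProcess(
                neuron_ids=(0,), kind="periodic", period=200.0,
                rate_fn=lambda t: 0.2 if t < 100.0 else 0.0)],
            synapses=[], input_neuron_ids=(0,))
        rec = run(net, 6000.0, dt=0.5, seed=14).spikes
        phases = rec.times % 200.0
        assert np.all(phases <= 100.5)
        assert len(rec) > 50


class TestFastPathEquivalence:
    def test_jitted_path_bitwise_matches_generic(self, rect_pair,
                                                 monkeypatch):
        """The accelerated rectangular-pulse path consumes the same
        uniform stream and reproduces the generic stepping bit-for-bit."""
        from stospike import simulate as sim
        if not sim._HAVE_NUMBA:
            pytest.skip("accelerated path not available")
        fast = run(rect_pair, 20000.0, dt=0.5, seed=42).spikes
        monkeypatch.setattr(sim, "_HAVE_NUMBA", False)
        fresh = NetworkModel(neurons=list(rect_pair.neurons),
                             synapses=list(rect_pair.synapses))
        slow = run(fresh, 20000.0, dt=0.5, seed=42).spikes
        assert fast == slow
        assert len(fast) > 10


class TestPreparatoryProtocol:
    def _net(self):
        neurons = [NeuronParams(hazard_threshold=-63.0, refractory_abs=2.0),
                   NeuronParams(hazard_threshold=-63.0, refractory_abs=2.0),
                   NeuronParams(refractory_abs=0.0)]
        synapses = [SynapseParams(pre=2, post=0, weight=8.0, delay=1.0,
                                  kind="current-rect", pulse_length=5.0),
                    SynapseParams(pre=0, post=1, weight=6.0, delay=1.0,
                                  kind="current-rect", pulse_length=5.0)]
        return NetworkModel(neurons=neurons, synapses=synapses,
                            input_neuron_ids=(2,))

    def test_same_prep_seed_same_history_divergent_future(self):
        net = self._net()
        prep = [InputProcess(neuron_ids=(2,), kind="constant", rate=0.05)]
        st1, rec1 = prepare_initial_state(net, prep, 500.0, prep_seed=4,
                                          main_seed=100, dt=0.5)
        st2, rec2 = prepare_initial_state(net, prep, 500.0, prep_seed=4,
                                          main_seed=200, dt=0.5)
        assert rec1 == rec2                       # identical history t < 0
        assert np.all(rec1.times <= 0.0)
        f1 = run(net, 3000.0, dt=0.5, initial_state=st1).spikes
        f2 = run(net, 3000.0, dt=0.5, initial_state=st2).spikes
        assert f1 != f2                           # divergent future t > 0

    def test_silent_prep_yields_resting_state(self):
        # cold neurons (default threshold) and no preparatory drive
        neurons = [NeuronParams(), NeuronParams(),
                   NeuronParams(refractory_abs=0.0)]
        synapses = [SynapseParams(pre=2, post=0, weight=8.0, delay=1.0,
                                  kind="current-rect", pulse_length=5.0)]
        net = NetworkModel(neurons=neurons, synapses=synapses,
                           input_neuron_ids=(2,))
        prep = [InputProcess(neuron_ids=(2,), kind="constant", rate=0.0)]
        st, rec = prepare_initial_state(net, prep, 300.0, prep_seed=1,
                                        main_seed=2, dt=0.5)
        assert len(rec) == 0
        assert np.all(st.rect_level == 0.0)

    def test_prep_shorter_than_state_window_rejected(self):
        net = self._net()
        with pytest.raises(ValueError):
            prepare_initial_state(net, [], 50.0, prep_seed=1, main_seed=2,
                                  dt=0.5, state_window=100.0)

    def test_random_prep_rates_give_distinct_states(self):
        net = self._net()
        rng = np.random.default_rng(0)
        states = []
        for _ in range(3):
            rate = float(rng.uniform(0.0, 0.05))
            prep = [InputProcess(neuron_ids=(2,), kind="constant", rate=rate)]
            st, rec = prepare_initial_state(net, prep, 500.0,
                                            prep_seed=int(rng.integers(1e6)),
                                            main_seed=0, dt=0.5)
            states.append(len(rec))
        assert len(set(states)) > 1
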