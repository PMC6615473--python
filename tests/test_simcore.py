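"""LIF dynamics, spike propagation, STDP, and network serialization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memnet.simcore import (LIFParams, Network, NeuronState, SpikeRecord,
                            STDPParams, Synapse, run, step_neuron,
                            stdp_update)


def chain_net(weight=50.0, delay=3, v_th=45.0):
    """input -> memory single-synapse chain."""
    net = Network()
    a = net.add_neuron("input", part=0, x=0, y=0)
    b = net.add_neuron("memory", part=0, x=0, y=0)
    net.add_synapse(Synapse(a, b, weight, delay))
    return net, a, b


class TestStepNeuron:
    def test_quiescence(self):
        state, fired = step_neuron(NeuronState(v=0.0), 0.0, LIFParams())
        assert state.v == 0.0 and not fired

    def test_one_step_leak(self):
        state, fired = step_neuron(NeuronState(v=10.0), 0.0,
                                   LIFParams(beta=0.9, v_th=100))
        assert state.v == pytest.approx(9.0) and not fired

    def test_threshold_is_inclusive(self):
        p = LIFParams(beta=0.9, v_th=45.0, v_reset=0.0)
        state, fired = step_neuron(NeuronState(v=0.0), 45.0, p, t=7.0)
        assert fired and state.v == 0.0 and state.last_spike_times == [7.0]

    def test_just_below_threshold_no_spike(self):
        state, fired = step_neuron(NeuronState(v=0.0), 44.999, LIFParams())
        assert not fired

    def test_no_input_decay_closed_form(self):
        # with no input, V(t) = beta^t * V(0) exactly
        p = LIFParams(beta=0.8, v_th=1e9)
        state = NeuronState(v=5.0)
        for t in range(1, 20):
            state, _ = step_neuron(state, 0.0, p)
            assert state.v == pytest.approx(5.0 * 0.8 ** t)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            LIFParams(beta=1.2)
        with pytest.raises(ValueError):
            LIFParams(beta=1.0)
        with pytest.raises(ValueError):
            LIFParams(v_th=0.0, v_reset=0.0)
        assert LIFParams.allow_no_leak().beta == 1.0


class TestStdpUpdate:
    P = STDPParams(a_plus=1.0, a_minus=1.2, tau_plus=20, tau_minus=20,
                   w_max=100.0, soft_bound=False)

    def test_simultaneous_spikes_do_nothing(self):
        syn = Synapse(0, 1, 10.0)
        assert stdp_update(syn, 5.0, 5.0, self.P).weight == 10.0

    def test_causal_pairing_potentiates(self):
        syn = Synapse(0, 1, 10.0)
        out = stdp_update(syn, 10.0, 11.0, self.P)
        assert out.weight == pytest.approx(10.0 + math.exp(-1 / 20))

    def test_acausal_pairing_depresses(self):
        syn = Synapse(0, 1, 10.0)
        out = stdp_update(syn, 11.0, 10.0, self.P)
        assert out.weight == pytest.approx(10.0 - 1.2 * math.exp(-1 / 20))

    def test_lower_clip_at_zero(self):
        syn = Synapse(0, 1, 0.0)
        assert stdp_update(syn, 11.0, 10.0, self.P).weight == 0.0

    def test_upper_clip_at_w_max(self):
        p = STDPParams(a_plus=5.0, a_minus=1.0, w_max=10.0, soft_bound=False)
        syn = Synapse(0, 1, 9.9)
        assert stdp_update(syn, 10.0, 10.5, p).weight == 10.0

    @settings(deadline=None, max_examples=60)
    @given(dt=st.floats(0.1, 100.0), w=st.floats(1.0, 50.0))
    def test_sign_law_and_window_decay(self, dt, w):
        # potentiate iff pre precedes post; magnitude shrinks with the gap
        near = stdp_update(Synapse(0, 1, w), 0.0, dt, self.P).weight - w
        far = stdp_update(Synapse(0, 1, w), 0.0, dt + 5, self.P).weight - w
        assert near > 0 and far > 0 and far < near
        dep = stdp_update(Synapse(0, 1, w), dt, 0.0, self.P).weight - w
        assert dep < 0 or w == 0.0


class TestSynapse:
    def test_no_self_loops(self):
        with pytest.raises(ValueError):
            Synapse(3, 3, 10.0)

    def test_delay_positive_integer(self):
        with pytest.raises(ValueError):
            Synapse(0, 1, 10.0, delay=0)

    def test_weight_clipped_to_range(self):
        assert Synapse(0, 1, 150.0).weight == 100.0
        assert Synapse(0, 1, -5.0).weight == 0.0


class TestRun:
    def test_empty_injection_empty_record(self):
        net, _, _ = chain_net()
        record = run(net, [], duration=50)
        assert len(record) == 0

    def test_single_path_propagation(self):
        # spike at t=5 over weight-50/delay-3 synapse fires memory at t=8
        net, a, b = chain_net(weight=50.0, delay=3)
        record = run(net, [(0, 5.0)], duration=20,
                     lif=LIFParams(beta=0.9, v_th=45.0))
        assert record.spikes_of(a) == [5.0]
        assert record.spikes_of(b) == [8.0]

    def test_subthreshold_weight_no_memory_spike(self):
        net, _, b = chain_net(weight=40.0)
        record = run(net, [(0, 5.0)], duration=20)
        assert record.spikes_of(b) == []

    def test_determinism(self, spike_sequences):
        from memnet.topology import LayerSpec, build_initial_network
        net = build_initial_network(LayerSpec(n_output=2))
        r1 = run(net, spike_sequences[0], duration=260)
        r2 = run(net, spike_sequences[0], duration=260)
        assert r1.events == r2.events

    def test_causality_against_event_oracle(self, rng):
        # clock-driven propagation matches a brute-force event queue on
        # random feed-forward networks
        for _ in range(5):
            net = Network()
            inputs = [net.add_neuron("input") for _ in range(4)]
            mems = [net.add_neuron("memory") for _ in range(6)]
            syns = []
            for i in inputs:
                for m in mems:
                    if rng.random() < 0.5:
                        s = Synapse(i, m, float(rng.integers(20, 60)),
                                    int(rng.integers(1, 6)))
                        if net.add_synapse(s):
                            syns.append(s)
            inj = [(c, float(rng.integers(0, 10))) for c in range(4)]
            lif = LIFParams(beta=0.9, v_th=45.0)
            record = run(net, inj, duration=40, lif=lif)

            # oracle: per-neuron arrival lists, explicit LIF loop
            arrivals = {m: {} for m in mems}
            for s in syns:
                t_in = dict(inj)[s.pre]
                t_arr = int(round(t_in)) + s.delay
                arrivals[s.post][t_arr] = arrivals[s.post].get(t_arr, 0) + s.weight
            for m in mems:
                v, expected = 0.0, []
                for t in range(40):
                    v = 0.9 * v + arrivals[m].get(t, 0.0)
                    if v >= 45.0:
                        expected.append(float(t))
                        v = 0.0
                assert record.spikes_of(m) == expected

    def test_weights_stay_in_bounds_after_stdp(self, spike_sequences):
        from memnet.growth import GrowthConfig, grow_connections, wire_output
        from memnet.topology import LayerSpec, build_initial_network
        net = build_initial_network(LayerSpec(n_output=2))
        record = run(net, spike_sequences[0], duration=260)
        grow_connections(record, net, GrowthConfig())
        wire_output(record, net, 0, GrowthConfig())
        run(net, spike_sequences[0], duration=260, stdp_on=True,
            stdp=STDPParams(a_plus=5.0, a_minus=5.0))
        for s in net.synapses:
            assert 0.0 <= s.weight <= 100.0

    def test_non_plastic_weights_untouched_by_stdp(self, spike_sequences):
        from memnet.topology import LayerSpec, build_initial_network
        net = build_initial_network(LayerSpec(n_output=2))
        before = [s.weight for s in net.synapses]
        run(net, spike_sequences[1], duration=260, stdp_on=True,
            stdp=STDPParams(a_plus=10.0, a_minus=10.0, w_max_out=0.5))
        assert [s.weight for s in net.synapses] == before

    def test_dangling_synapse_rejected(self):
        net, _, _ = chain_net()
        net.synapses[0].post = 99
        with pytest.raises(ValueError):
            run(net, [], duration=10)

    def test_record_time_sorted_one_spike_per_step(self, spike_sequences):
        from memnet.topology import LayerSpec, build_initial_network
        net = build_initial_network(LayerSpec(n_output=1))
        record = run(net, spike_sequences[4], duration=260)
        times = [t for _, t in record.events]
        assert times == sorted(times)
        assert len(set(record.events)) == len(record.events)


class TestNetworkSerialization:
    def test_json_round_trip(self, tmp_path, spike_sequences):
        from memnet.growth import GrowthConfig, grow_connections, wire_output
        from memnet.topology import LayerSpec, build_initial_network
        net = build_initial_network(LayerSpec(n_output=3))
        record = run(net, spike_sequences[2], duration=260)
        grow_connections(record, net, GrowthConfig())
        wire_output(record, net, 1, GrowthConfig())
        path = tmp_path / "net.json"
        net.save(path)
        back = Network.load(path)
        assert back.layer == net.layer
        assert back.part == net.part
        assert back.x == net.x and back.y == net.y
        assert [(s.pre, s.post, s.weight, s.delay, s.plastic)
                for s in back.synapses] == \
               [(s.pre, s.post, s.weight, s.delay, s.plastic)
                for s in net.synapses]

    def test_duplicate_edge_keeps_first(self):
        net, a, b = chain_net(weight=50.0)
        assert not net.add_synapse(Synapse(a, b, 10.0))
        assert net.get_synapse(a, b).weight == 50.0

    def test_spike_record_helpers(self):
        rec = SpikeRecord(events=[(3, 1.0), (5, 1.0), (3, 4.0)])
        assert rec.first_spike_times() == {3: 1.0, 5: 1.0}
        assert rec.fired() == {3, 5}
        assert rec.spikes_of(3) == [1.0, 4.0]
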