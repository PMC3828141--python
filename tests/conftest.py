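import numpy as np
import pytest

from stospike.network import NetworkModel, NeuronParams, SynapseParams


@pytest.fixture
def rect_pair():
    """Two-neuron rectangular-pulse network (exc -> inh -> exc loop)."""
    neurons = [
        NeuronParams(hazard_threshold=-66.0, refractory_abs=2.0, rate_cap=0.5),
        NeuronParams(hazard_threshold=-64.0, refractory_abs=3.0,
                     rate_cap=0.5, is_inhibitory=True),
    ]
    synapses = [
        SynapseParams(pre=0, post=1, weight=5.0, delay=1.0,
                      kind="current-rect", pulse_length=4.0),
        SynapseParams(pre=1, post=0, weight=8.0, delay=2.0,
                      kind="current-rect", pulse_length=6.0),
    ]
    return NetworkModel(neurons=neurons, synapses=synapses)


@pytest.fixture
def single_hot_neuron():
    """One neuron with a potential-clamped firing rate at its cap (0.2/ms)."""
    p = NeuronParams(hazard_threshold=-66.0, bias_potential=12.0,
                     refractory_abs=2.0, rate_cap=0.2)
    # rate at rest: r0 * exp((EL + 12 - VT)/dV) = 0.01*e^4, capped at 0.2
    return NetworkModel(neurons=[p], synapses=[])
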