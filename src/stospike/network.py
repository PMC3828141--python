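"""Domain types for stochastic spiking networks.

A :class:`NetworkModel` is a directed graph of escape-noise leaky
integrate-and-fire neurons (:class:`NeuronParams`) connected by static
or dynamic synapses (:class:`SynapseParams`), optionally driven by
Poisson input processes (:class:`InputProcess`).  Spike data is carried
between modules as a :class:`SpikeRecord`.

Units follow the conventions of the field: time in ms, potentials in mV,
conductances in nS, capacitance in nF, currents in nA, rates in 1/ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "NeuronParams", "SynapseParams", "STPParams", "InputProcess",
    "NetworkModel", "SpikeRecord", "ThresholdModulation",
]


@dataclass(frozen=True)
class NeuronParams:
    """Parameters of a single escape-noise leaky integrate-and-fire neuron.

    The escape-noise (hazard) mechanism replaces the hard threshold of a
    deterministic LIF neuron with a voltage-dependent instantaneous firing
    rate ``r(V) = min(r0 * exp((V - V_T) / dV), r_max)``, so spiking is a
    point process whose intensity follows the membrane potential.

    Defaults are typical cortical point-neuron values; membrane time
    constant C_m/g_L = 20 ms.
    """

    leak_conductance: float = 10.0       # g_L, nS
    membrane_capacitance: float = 0.2    # C_m, nF
    resting_potential: float = -70.0     # E_L, mV
    reversal_exc: float = 0.0            # E_exc, mV
    reversal_inh: float = -75.0          # E_inh, mV
    hazard_base_rate: float = 0.01       # r0, 1/ms (rate at V == V_T)
    hazard_threshold: float = -55.0      # V_T, mV
    hazard_slope: float = 2.0            # dV, mV
    rate_cap: float = 1.0                # r_max, 1/ms (bounded-rate assumption)
    refractory_abs: float = 3.0          # ms
    bias_current: float = 0.0            # nA
    bias_potential: float = 0.0          # mV, direct offset on the hazard potential
    is_inhibitory: bool = False

    def __post_init__(self) -> None:
        if not (self.hazard_base_rate > 0):
            raise ValueError("hazard_base_rate r0 must be > 0")
        if not (self.hazard_slope > 0):
            raise ValueError("hazard_slope dV must be > 0")
        if not (self.rate_cap >= self.hazard_base_rate):
            raise ValueError("rate_cap r_max must be >= r0")
        if self.refractory_abs < 0:
            raise ValueError("refractory_abs must be >= 0")
        if not (self.reversal_exc > self.resting_potential > self.reversal_inh):
            raise ValueError(
                "require reversal_exc > resting_potential > reversal_inh"
            )


@dataclass(frozen=True)
class STPParams:
    """Short-term plasticity parameters (utilization / depression / facilitation).

    U is the utilization of synaptic efficacy by the first spike after rest,
    D the depression (vesicle recovery) time constant in ms, and F the
    facilitation time constant in ms.
    """

    U: float
    D: float
    F: float

    def __post_init__(self) -> None:
        if not (0 < self.U <= 1):
            raise ValueError("U must be in (0, 1]")
        if not (self.D > 0 and self.F > 0):
            raise ValueError("D and F must be > 0")


@dataclass(frozen=True)
class SynapseParams:
    """A single synapse.

    ``weight`` is always nonnegative bookkeeping; the *sign* of the effect
    is determined by the presynaptic neuron's ``is_inhibitory`` flag.
    ``kind`` selects the postsynaptic model:

    - ``"conductance-exp"``: exponentially decaying conductance transient
      (amplitude ``weight`` nS) towards the appropriate reversal potential.
    - ``"current-rect"``: rectangular potential pulse of length
      ``pulse_length`` ms and amplitude ``weight`` mV added directly to the
      potential seen by the hazard function (point-process simplification;
      this is what makes event-driven simulation of such networks exact).
    """

    pre: int
    post: int
    weight: float
    delay: float = 1.0
    kind: str = "conductance-exp"
    pulse_length: float = 10.0
    stp: Optional[STPParams] = None
    release_probability: float = 1.0   # hook for stochastic-release noise, default off

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("weight must be >= 0 (sign comes from presynaptic type)")
        if self.kind not in ("conductance-exp", "current-rect"):
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if self.kind == "current-rect" and not (self.pulse_length > 0):
            raise ValueError("pulse_length must be > 0 for current-rect synapses")
        if not (0 < self.release_probability <= 1):
            raise ValueError("release_probability must be in (0, 1]")


@dataclass(frozen=True)
class InputProcess:
    """Poisson spike sources attached to dedicated input neurons.

    ``kind`` is one of ``constant``, ``periodic``, ``markov-modulated`` or
    ``schedule``.  ``rate`` is the rate in 1/ms; for ``periodic`` the rate
    is ``rate_fn(t mod period)``; for ``markov-modulated`` a finite-state
    chain (``modulator``) selects among rates; ``schedule`` uses a
    piecewise-constant (times, rates) table.
    """

    neuron_ids: tuple
    kind: str = "constant"
    rate: float = 0.0                     # 1/ms, for constant kind
    rate_fn: Optional[Callable[[float], float]] = None   # periodic kind
    period: Optional[float] = None        # ms, periodic kind
    schedule: Optional[tuple] = None      # ((t0, r0), (t1, r1), ...) piecewise-const
    modulator: Optional[dict] = None      # {"rates": [...], "transition": [[...]], "dwell": ms}
    per_neuron_rates: Optional[tuple] = None  # overrides `rate` per neuron id

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "periodic", "markov-modulated", "schedule"):
            raise ValueError(f"unknown input kind {self.kind!r}")
        if self.kind == "constant" and self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.kind == "periodic":
            if self.rate_fn is None or self.period is None or self.period <= 0:
                raise ValueError("periodic input needs rate_fn and period > 0")

    def rate_at(self, t: float, neuron_index: int = 0, mod_state: int = 0) -> float:
        """Instantaneous rate lambda(t) >= 0 for one of the process's neurons."""
        if self.kind == "constant":
            if self.per_neuron_rates is not None:
                return self.per_neuron_rates[neuron_index]
            return self.rate
        if self.kind == "periodic":
            return max(0.0, self.rate_fn(t % self.period))
        if self.kind == "schedule":
            r = 0.0
            for t0, r0 in self.schedule:
                if t >= t0:
                    r = r0
            return r
        # markov-modulated: caller supplies the current modulator state
        return self.modulator["rates"][mod_state]


@dataclass(frozen=True)
class ThresholdModulation:
    """Periodic offset added to every neuron's hazard threshold V_T.

    Models a global oscillation imposed on neuronal excitability:
    offset(t) = amplitude * sin(2*pi*t/period + phase0).
    """

    amplitude: float   # mV
    period: float      # ms
    phase0: float = 0.0

    def offset(self, t) -> float:
        return self.amplitude * np.sin(2 * np.pi * t / self.period + self.phase0)


@dataclass
class NetworkModel:
    """A directed network of stochastic neurons and (dynamic) synapses."""

    neurons: list
    synapses: list
    inputs: list = field(default_factory=list)
    threshold_modulation: Optional[ThresholdModulation] = None
    # ids of dedicated input neurons (spike by rate, membrane ignored)
    input_neuron_ids: tuple = ()
    metadata: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def validate(self, dt: Optional[float] = None) -> None:
        n = self.n_neurons
        for s in self.synapses:
            if not (0 <= s.pre < n and 0 <= s.post < n):
                raise ValueError(f"synapse {s.pre}->{s.post} references missing neuron")
            if dt is not None and s.delay < dt:
                raise ValueError(
                    f"synapse delay {s.delay} ms < simulation step {dt} ms"
                )
        for ip in self.inputs:
            for i in ip.neuron_ids:
                if not (0 <= i < n):
                    raise ValueError(f"input process references missing neuron {i}")

    def with_synapses(self, synapses) -> "NetworkModel":
        return NetworkModel(
            neurons=list(self.neurons), synapses=list(synapses),
            inputs=list(self.inputs),
            threshold_modulation=self.threshold_modulation,
            input_neuron_ids=self.input_neuron_ids,
            metadata=dict(self.metadata),
        )


class SpikeRecord:
    """Time-sorted spike events ``(neuron_id, time_ms)``.

    The universal exchange object between the simulator and every
    analysis module.  Backed by two parallel numpy arrays.
    """

    def __init__(self, neuron_ids: Iterable[int] = (), times: Iterable[float] = ()):
        self.neuron_ids = np.asarray(list(neuron_ids) if not isinstance(
            neuron_ids, np.ndarray) else neuron_ids, dtype=np.int64)
        self.times = np.asarray(list(times) if not isinstance(
            times, np.ndarray) else times, dtype=np.float64)
        if self.neuron_ids.shape != self.times.shape:
            raise ValueError("neuron_ids and times must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be sorted ascending")

    def __len__(self) -> int:
        return int(self.times.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpikeRecord):
            return NotImplemented
        return (np.array_equal(self.neuron_ids, other.neuron_ids)
                and np.array_equal(self.times, other.times))

    def __repr__(self) -> str:
        return f"SpikeRecord(n_events={len(self)})"

    def spikes_of(self, neuron_id: int) -> np.ndarray:
        """All spike times of one neuron, ascending."""
        return self.times[self.neuron_ids == neuron_id]

    def in_window(self, t0: float, t1: float) -> "SpikeRecord":
        """Events with time in the half-open window (t0, t1]."""
        lo = np.searchsorted(self.times, t0, side="right")
        hi = np.searchsorted(self.times, t1, side="right")
        return SpikeRecord(self.neuron_ids[lo:hi], self.times[lo:hi])

    def shifted(self, offset: float) -> "SpikeRecord":
        return SpikeRecord(self.neuron_ids.copy(), self.times + offset)

    @staticmethod
    def concatenate(records: Sequence["SpikeRecord"]) -> "SpikeRecord":
        if not records:
            return SpikeRecord()
        ids = np.concatenate([r.neuron_ids for r in records])
        ts = np.concatenate([r.times for r in records])
        return SpikeRecord(ids, ts)

    def check_refractory(self, net: NetworkModel, tol: float = 1e-9) -> bool:
        """True iff consecutive spikes of every neuron are separated by
        at least that neuron's absolute refractory period."""
        for i in range(net.n_neurons):
            ts = self.spikes_of(i)
            if ts.size > 1:
                if np.any(np.diff(ts) < net.neurons[i].refractory_abs - tol):
                    return False
        return True
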