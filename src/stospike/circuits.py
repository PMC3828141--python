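"""Constructors for the network families used throughout the package.

- a laminar cortical-microcircuit template (three layers x {E, I} pools,
  data-based connectivity structure, Gamma-distributed weights,
  type-specific short-term plasticity, two Poisson input streams);
- a hand-tuned 10-neuron small column;
- a sparsely active E/I network;
- sequence (synfire-like chain) networks with one or two competing
  subnetworks;
- a bistable attractor network of two mutually inhibiting populations;
- readout (observer) neuron attachment.

The laminar template's numeric tables are shipped as an editable,
clearly marked placeholder transcription that preserves the qualitative
structure of data-based cortical column models (denser within-layer
connectivity, feedforward L4 -> L2/3 -> L5 excitation, type-specific
short-term plasticity classes); no quantitative claim rests on these
placeholder values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .network import (InputProcess, NetworkModel, NeuronParams, STPParams,
                      SynapseParams)

__all__ = [
    "POOLS", "LaminarTemplate", "ReadoutSpec", "default_laminar_template",
    "build_laminar", "scale_weights", "build_sparse", "build_sequence",
    "build_bistable", "build_small_column", "attach_readout",
]

POOLS = ("L23E", "L23I", "L4E", "L4I", "L5E", "L5I")

# Short-term plasticity classes by (presynaptic, postsynaptic) type:
# mean (U, D ms, F ms); per-neuron draws are Gaussian with SD = 50% of
# the mean, truncated to valid ranges.  These are the standard
# depressing/facilitating class values used with the Markram-Tsodyks
# synapse model.
STP_CLASSES: Dict[Tuple[str, str], Tuple[float, float, float]] = {
    ("E", "E"): (0.5, 1100.0, 50.0),
    ("E", "I"): (0.05, 125.0, 1200.0),
    ("I", "E"): (0.25, 700.0, 20.0),
    ("I", "I"): (0.32, 144.0, 60.0),
}


def _draw_stp(rng: np.random.Generator, pre_type: str,
              post_type: str) -> STPParams:
    U0, D0, F0 = STP_CLASSES[(pre_type, post_type)]
    U = float(np.clip(rng.normal(U0, 0.5 * U0), 0.01, 1.0))
    D = float(max(1.0, rng.normal(D0, 0.5 * D0)))
    F = float(max(1.0, rng.normal(F0, 0.5 * F0)))
    return STPParams(U=U, D=D, F=F)


def _mean_stp(pre_type: str, post_type: str) -> STPParams:
    """Class-mean short-term plasticity (used by the demo circuits, which
    fix dynamic synapse parameters at the class means)."""
    U0, D0, F0 = STP_CLASSES[(pre_type, post_type)]
    return STPParams(U=U0, D=D0, F=F0)


def _gamma_weight(rng: np.random.Generator, mean: float, cv: float,
                  size=None):
    if mean <= 0:
        return np.zeros(size) if size else 0.0
    shape = 1.0 / cv**2
    scale = mean * cv**2
    return rng.gamma(shape, scale, size=size)


@dataclass
class LaminarTemplate:
    """Config-driven laminar column template.

    ``conn_prob``/``conn_weight``/``conn_delay`` are keyed by
    (pre_pool, post_pool); weights are (mean nS, CV) of a Gamma
    distribution.  ``input_streams`` each attach ``n`` Poisson neurons
    at a fixed rate (1/ms) to target pools with a given probability.
    """

    pool_fractions: Dict[str, float]
    conn_prob: Dict[Tuple[str, str], float]
    conn_weight: Dict[Tuple[str, str], Tuple[float, float]]
    conn_delay: Dict[Tuple[str, str], float]
    input_streams: List[dict]
    background_current: Dict[str, float]    # nA per pool (placeholder values)
    n_reference: int = 560                  # size the weights are tuned at

    def to_dict(self) -> dict:
        j = lambda k: f"{k[0]}->{k[1]}"
        return {
            "pool_fractions": dict(self.pool_fractions),
            "conn_prob": {j(k): v for k, v in self.conn_prob.items()},
            "conn_weight": {j(k): list(v) for k, v in self.conn_weight.items()},
            "conn_delay": {j(k): v for k, v in self.conn_delay.items()},
            "input_streams": [dict(s, weight=list(s["weight"]))
                              for s in self.input_streams],
            "background_current": dict(self.background_current),
            "n_reference": self.n_reference,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LaminarTemplate":
        split = lambda k: tuple(k.split("->"))
        return cls(
            pool_fractions=dict(d["pool_fractions"]),
            conn_prob={split(k): v for k, v in d["conn_prob"].items()},
            conn_weight={split(k): tuple(v)
                         for k, v in d["conn_weight"].items()},
            conn_delay={split(k): v for k, v in d["conn_delay"].items()},
            input_streams=[dict(s, weight=tuple(s["weight"]))
                           for s in d["input_streams"]],
            background_current=dict(d["background_current"]),
            n_reference=d.get("n_reference", 560),
        )

    def validate(self) -> None:
        if abs(sum(self.pool_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("pool fractions must sum to 1")
        for k, p in self.conn_prob.items():
            if not (0 <= p <= 1):
                raise ValueError(f"connection probability {k} out of [0,1]")
        for k, (m, cv) in self.conn_weight.items():
            if m < 0 or cv <= 0:
                raise ValueError(f"bad weight spec for {k}")


def default_laminar_template() -> LaminarTemplate:
    """Placeholder transcription of a data-based laminar column.

    Values preserve the qualitative structure (within-layer density,
    L4 -> L2/3 -> L5 feedforward excitation, strong local inhibition)
    and are tuned for the default activity band; treat them as
    editable configuration, not as data.
    """
    P: Dict[Tuple[str, str], float] = {}
    W: Dict[Tuple[str, str], Tuple[float, float]] = {}
    D: Dict[Tuple[str, str], float] = {}

    def C(pre, post, p, w, cv=0.7, d=1.0):
        P[(pre, post)] = p
        W[(pre, post)] = (w, cv)
        D[(pre, post)] = d

    # within-layer connectivity (E->E, E->I, I->E, I->I per layer)
    for L in ("L23", "L4", "L5"):
        C(L + "E", L + "E", 0.15, 1.3)
        C(L + "E", L + "I", 0.30, 1.6)
        C(L + "I", L + "E", 0.35, 2.8)
        C(L + "I", L + "I", 0.25, 2.2)
    # feedforward / feedback excitation between layers
    C("L4E", "L23E", 0.28, 1.4)
    C("L4E", "L23I", 0.10, 1.4)
    C("L23E", "L5E", 0.25, 1.4)
    C("L23E", "L5I", 0.08, 1.4)
    C("L5E", "L23E", 0.03, 1.0)
    C("L4E", "L5E", 0.05, 1.0)
    C("L23E", "L4E", 0.03, 1.0)
    C("L5E", "L4E", 0.02, 1.0)
    # weak cross-layer inhibition
    C("L23I", "L4E", 0.05, 1.5)
    C("L4I", "L23E", 0.05, 1.5)

    streams = [
        {"n": 40, "rate": 0.02,
         "targets": {"L4E": 0.25, "L4I": 0.15}, "weight": (1.8, 0.7)},
        {"n": 40, "rate": 0.02,
         "targets": {"L23E": 0.25, "L23I": 0.15}, "weight": (1.8, 0.7)},
    ]
    background = {"L23E": 0.10, "L23I": 0.08, "L4E": 0.10,
                  "L4I": 0.08, "L5E": 0.11, "L5I": 0.08}
    return LaminarTemplate(
        pool_fractions={"L23E": 0.30, "L23I": 0.10, "L4E": 0.20,
                        "L4I": 0.10, "L5E": 0.20, "L5I": 0.10},
        conn_prob=P, conn_weight=W, conn_delay=D,
        input_streams=streams, background_current=background,
    )


def _pool_slices(template: LaminarTemplate, n_total: int) -> Dict[str, np.ndarray]:
    sizes = {p: int(round(template.pool_fractions[p] * n_total)) for p in POOLS}
    drift = n_total - sum(sizes.values())
    sizes["L23E"] += drift
    ids: Dict[str, np.ndarray] = {}
    start = 0
    for p in POOLS:
        ids[p] = np.arange(start, start + sizes[p])
        start += sizes[p]
    return ids


def build_laminar(template: LaminarTemplate, n_total: int,
                  seed: Optional[int] = None) -> NetworkModel:
    """Instantiate the laminar column with ``n_total`` neurons.

    Bernoulli connectivity per pool pair, Gamma-distributed weights,
    per-presynaptic-neuron short-term plasticity draws by connection
    type, two Poisson input streams of 40 neurons each, and background
    bias currents.  Deterministic given the seed.
    """
    template.validate()
    if n_total < 60:
        raise ValueError("need at least 60 neurons (10 per pool)")
    rng = np.random.default_rng(seed)
    ids = _pool_slices(template, n_total)

    neurons: List[NeuronParams] = []
    for p in POOLS:
        inh = p.endswith("I")
        for _ in ids[p]:
            neurons.append(NeuronParams(
                is_inhibitory=inh,
                refractory_abs=2.0 if inh else 3.0,
                bias_current=template.background_current.get(p, 0.0),
            ))

    # per-(presynaptic neuron, post type) STP draws shared by all of that
    # neuron's synapses onto the type
    stp_cache: Dict[Tuple[int, str], STPParams] = {}

    def stp_for(pre_id: int, pre_type: str, post_type: str) -> STPParams:
        key = (pre_id, post_type)
        if key not in stp_cache:
            stp_cache[key] = _draw_stp(rng, pre_type, post_type)
        return stp_cache[key]

    synapses: List[SynapseParams] = []
    for (pre_pool, post_pool), p in template.conn_prob.items():
        if p <= 0:
            continue
        pre_ids, post_ids = ids[pre_pool], ids[post_pool]
        mask = rng.random((pre_ids.size, post_ids.size)) < p
        if pre_pool == post_pool:
            np.fill_diagonal(mask, False)
        wm, cv = template.conn_weight[(pre_pool, post_pool)]
        delay = template.conn_delay.get((pre_pool, post_pool), 1.0)
        rr, cc = np.nonzero(mask)
        ws = _gamma_weight(rng, wm, cv, size=rr.size)
        pre_type = pre_pool[-1]
        post_type = post_pool[-1]
        for k in range(rr.size):
            pre_id = int(pre_ids[rr[k]])
            synapses.append(SynapseParams(
                pre=pre_id, post=int(post_ids[cc[k]]), weight=float(ws[k]),
                delay=delay, kind="conductance-exp",
                stp=stp_for(pre_id, pre_type, post_type)))

    # input streams: dedicated Poisson neurons appended after the circuit
    inputs: List[InputProcess] = []
    input_ids: List[int] = []
    for stream in template.input_streams:
        sids = []
        for _ in range(stream["n"]):
            neurons.append(NeuronParams(is_inhibitory=False, refractory_abs=0.0))
            sids.append(len(neurons) - 1)
        input_ids.extend(sids)
        wm, cv = stream["weight"]
        for pool, p in stream["targets"].items():
            mask = rng.random((len(sids), ids[pool].size)) < p
            rr, cc = np.nonzero(mask)
            ws = _gamma_weight(rng, wm, cv, size=rr.size)
            for k in range(rr.size):
                synapses.append(SynapseParams(
                    pre=sids[rr[k]], post=int(ids[pool][cc[k]]),
                    weight=float(ws[k]), delay=1.0, kind="conductance-exp"))
        inputs.append(InputProcess(neuron_ids=tuple(sids), kind="constant",
                                   rate=stream["rate"]))

    return NetworkModel(
        neurons=neurons, synapses=synapses, inputs=inputs,
        input_neuron_ids=tuple(input_ids),
        metadata={"kind": "laminar", "pools": {p: ids[p].tolist() for p in POOLS},
                  "n_total": n_total},
    )


def scale_weights(template: LaminarTemplate, n_ref: int,
                  n_new: int) -> LaminarTemplate:
    """Scale recurrent mean weights inversely with network size.

    Mean recurrent synaptic weights are multiplied by ``n_ref / n_new``
    so that total recurrent drive stays roughly size-invariant; input
    stream and background weights are untouched.
    """
    if n_ref <= 0 or n_new <= 0:
        raise ValueError("sizes must be positive")
    f = n_ref / n_new
    new_w = {k: (m * f, cv) for k, (m, cv) in template.conn_weight.items()}
    return replace(template, conn_weight=new_w)


# --------------------------------------------------------------------------
# sparse E/I network

def build_sparse(seed: Optional[int] = None, n_exc: int = 10,
                 n_inh: int = 10) -> NetworkModel:
    """Sparsely active network: sparse excitation, dense inhibition.

    Connection probabilities E->E = 0.1, E->I = 0.1, I->E = 0.9,
    I->I = 0.9; one excitatory and one inhibitory population of 10
    neurons each by default, driven by small bias currents.
    """
    rng = np.random.default_rng(seed)
    probs = {("E", "E"): 0.1, ("E", "I"): 0.1, ("I", "E"): 0.9, ("I", "I"): 0.9}
    weights = {("E", "E"): 1.5, ("E", "I"): 1.5, ("I", "E"): 2.5, ("I", "I"): 2.0}
    neurons = [NeuronParams(is_inhibitory=False, bias_current=0.13)
               for _ in range(n_exc)]
    neurons += [NeuronParams(is_inhibitory=True, bias_current=0.10,
                             refractory_abs=2.0) for _ in range(n_inh)]
    pools = {"E": list(range(n_exc)), "I": list(range(n_exc, n_exc + n_inh))}
    synapses: List[SynapseParams] = []
    for (a, b), p in probs.items():
        for i in pools[a]:
            for j in pools[b]:
                if i == j:
                    continue
                if rng.random() < p:
                    w = _gamma_weight(rng, weights[(a, b)], 0.7)
                    synapses.append(SynapseParams(
                        pre=i, post=j, weight=float(w), delay=1.0,
                        kind="conductance-exp",
                        stp=_mean_stp(a, b)))
    return NetworkModel(neurons=neurons, synapses=synapses,
                        metadata={"kind": "sparse", "pools": pools})


# --------------------------------------------------------------------------
# sequence (chain) networks

def build_sequence(n_chains: int, chain_length: int,
                   seed: Optional[int] = None,
                   xi_forward: float = 1.2, xi_backward: float = 0.8,
                   w0: float = 50.0, w0_trigger: float = 50.0,
                   n_inh: int = 5, delay: float = 2.0,
                   chain_threshold: float = -60.0) -> NetworkModel:
    """Networks producing stereotypical activity sequences.

    Each subnetwork has a spontaneously active trigger neuron, a chain
    of ``chain_length`` excitatory neurons and a pool of ``n_inh``
    inhibitory neurons.  Every chain neuron projects to all others in
    the same chain with strength decaying with index distance d as
    ``w0 * exp(-d / xi)``, with separate forward/backward decay
    constants; the trigger projects forward to the chain in the same
    way.  The chain drives the inhibitory pool, which projects back to
    the trigger and chain; with two subnetworks each inhibitory pool
    also targets the *other* subnetwork's trigger and chain, so only
    one sequence can unfold at a time.
    """
    if n_chains not in (1, 2):
        raise ValueError("n_chains must be 1 or 2")
    if chain_length < 3:
        raise ValueError("chain_length must be >= 3")
    rng = np.random.default_rng(seed)
    neurons: List[NeuronParams] = []
    synapses: List[SynapseParams] = []
    chains: List[dict] = []

    for c in range(n_chains):
        trig = len(neurons)
        neurons.append(NeuronParams(is_inhibitory=False, bias_current=0.14))
        chain = []
        for _ in range(chain_length):
            neurons.append(NeuronParams(
                is_inhibitory=False, bias_current=0.05,
                hazard_threshold=chain_threshold, refractory_abs=5.0))
            chain.append(len(neurons) - 1)
        inh = []
        for _ in range(n_inh):
            neurons.append(NeuronParams(is_inhibitory=True, bias_current=0.0,
                                        hazard_threshold=-62.0,
                                        refractory_abs=2.0))
            inh.append(len(neurons) - 1)
        chains.append({"trigger": trig, "chain": chain, "inh": inh})

        stp_ee = {i: _mean_stp("E", "E") for i in [trig] + chain}
        # trigger -> chain, forward decay
        for j, cj in enumerate(chain):
            w = w0_trigger * math.exp(-(j + 1) / xi_forward)
            synapses.append(SynapseParams(pre=trig, post=cj, weight=w,
                                          delay=delay, stp=stp_ee[trig]))
        # chain -> chain, forward and backward decay
        for i, ci in enumerate(chain):
            for j, cj in enumerate(chain):
                if i == j:
                    continue
                d = abs(j - i)
                xi = xi_forward if j > i else xi_backward
                w = w0 * math.exp(-d / xi)
                if w < 1e-4:
                    continue
                synapses.append(SynapseParams(pre=ci, post=cj, weight=w,
                                              delay=delay, stp=stp_ee[ci]))
        # chain -> inhibitory pool, pool -> trigger + chain
        for ci in chain:
            for ii in inh:
                synapses.append(SynapseParams(
                    pre=ci, post=ii, weight=8.0, delay=delay,
                    stp=_mean_stp("E", "I")))
        for ii in inh:
            for tgt in [trig] + chain:
                synapses.append(SynapseParams(
                    pre=ii, post=tgt, weight=12.0, delay=delay,
                    stp=_mean_stp("I", "E")))

    if n_chains == 2:
        for a, b in ((0, 1), (1, 0)):
            for ii in chains[a]["inh"]:
                for tgt in [chains[b]["trigger"]] + chains[b]["chain"]:
                    synapses.append(SynapseParams(
                        pre=ii, post=tgt, weight=15.0, delay=delay,
                        stp=_mean_stp("I", "E")))

    return NetworkModel(neurons=neurons, synapses=synapses,
                        metadata={"kind": "sequence", "chains": chains})


# --------------------------------------------------------------------------
# bistable network

def build_bistable(pool_size: int = 10, seed: Optional[int] = None,
                   w_self: float = 1.8, w_exc_inh: float = 3.0,
                   w_inh: float = 4.0, bias: float = 0.15) -> NetworkModel:
    """Two self-exciting populations with mutual di-synaptic inhibition.

    Pools A and B (``pool_size`` excitatory neurons each) excite
    themselves; each pool drives a small dedicated inhibitory pool that
    projects onto the *other* excitatory pool, so activity in one pool
    suppresses the other and the network hops stochastically between
    two attractor states.
    """
    rng = np.random.default_rng(seed)
    n_inh = max(2, pool_size // 3)
    neurons: List[NeuronParams] = []
    pools: Dict[str, list] = {}
    for name in ("A", "B"):
        pools[name] = []
        for _ in range(pool_size):
            neurons.append(NeuronParams(is_inhibitory=False, bias_current=bias))
            pools[name].append(len(neurons) - 1)
    for name in ("A", "B"):
        pools["I" + name] = []
        for _ in range(n_inh):
            neurons.append(NeuronParams(is_inhibitory=True, bias_current=0.0,
                                        refractory_abs=2.0))
            pools["I" + name].append(len(neurons) - 1)

    synapses: List[SynapseParams] = []
    for name in ("A", "B"):
        other = "B" if name == "A" else "A"
        for i in pools[name]:
            for j in pools[name]:
                if i != j and rng.random() < 0.8:
                    synapses.append(SynapseParams(
                        pre=i, post=j, weight=float(_gamma_weight(rng, w_self, 0.5)),
                        delay=1.0, stp=_mean_stp("E", "E")))
            for j in pools["I" + name]:
                if rng.random() < 0.9:
                    synapses.append(SynapseParams(
                        pre=i, post=j, weight=w_exc_inh, delay=1.0,
                        stp=_mean_stp("E", "I")))
        for i in pools["I" + name]:
            for j in pools[other]:
                if rng.random() < 0.9:
                    synapses.append(SynapseParams(
                        pre=i, post=j, weight=w_inh, delay=1.0,
                        stp=_mean_stp("I", "E")))
    return NetworkModel(neurons=neurons, synapses=synapses,
                        metadata={"kind": "bistable", "pools": pools})


# --------------------------------------------------------------------------
# small 10-neuron column

def build_small_column(seed: Optional[int] = 7) -> NetworkModel:
    """Hand-tuned 10-neuron microcircuit.

    A miniature laminar column (L2/3: 2E+1I, L4: 2E+1I, L5: 3E+1I),
    wired to echo the laminar template's structure, with two synaptic
    weights boosted by the documented factors 5 (neuron 2 -> 7) and 10
    (neuron 7 -> 8) to strengthen activity and correlations among the
    highlighted neurons (1-based labels), and small bias currents to
    shift the circuit into a responsive regime.
    """
    rng = np.random.default_rng(seed)
    # 0-based: L23E = 0,1; L23I = 2; L4E = 3,4; L4I = 5; L5E = 6,7,8; L5I = 9
    layout = {"L23E": [0, 1], "L23I": [2], "L4E": [3, 4], "L4I": [5],
              "L5E": [6, 7, 8], "L5I": [9]}
    inh_ids = {2, 5, 9}
    bias = {0: 0.12, 1: 0.12, 2: 0.04, 3: 0.13, 4: 0.13, 5: 0.04,
            6: 0.11, 7: 0.11, 8: 0.11, 9: 0.04}
    neurons = [NeuronParams(is_inhibitory=(i in inh_ids),
                            refractory_abs=2.0 if i in inh_ids else 3.0,
                            bias_current=bias[i]) for i in range(10)]
    edges = [
        (0, 1, 1.5), (1, 0, 1.5), (0, 2, 1.8), (1, 2, 1.8),
        (2, 0, 2.5), (2, 1, 2.5),
        (3, 4, 1.5), (4, 3, 1.5), (3, 5, 1.8), (4, 5, 1.8),
        (5, 3, 2.5), (5, 4, 2.5),
        (3, 0, 1.6), (4, 1, 1.6),                      # L4 -> L2/3
        (0, 6, 1.6), (1, 6, 1.6), (1, 8, 1.6),         # L2/3 -> L5
        (6, 7, 1.2), (7, 8, 1.2), (8, 6, 1.2),
        (6, 9, 1.8), (7, 9, 1.8), (8, 9, 1.8),
        (9, 6, 2.5), (9, 7, 2.5), (9, 8, 2.5),
    ]
    boosted = {(1, 6): 5.0, (6, 7): 10.0}   # 1-based (2 -> 7) and (7 -> 8)
    synapses = []
    for pre, post, w in edges:
        mult = boosted.get((pre, post), 1.0)
        a = "I" if pre in inh_ids else "E"
        b = "I" if post in inh_ids else "E"
        synapses.append(SynapseParams(pre=pre, post=post, weight=w * mult,
                                      delay=1.0, stp=_draw_stp(rng, a, b)))
    # two input neurons standing in for afferent streams
    neurons.append(NeuronParams(refractory_abs=0.0))
    neurons.append(NeuronParams(refractory_abs=0.0))
    in_a, in_b = 10, 11
    for tgt in (0, 1, 3, 4):
        synapses.append(SynapseParams(pre=in_a, post=tgt, weight=1.6, delay=1.0))
    for tgt in (3, 4, 6, 7, 8):
        synapses.append(SynapseParams(pre=in_b, post=tgt, weight=1.6, delay=1.0))
    inputs = [InputProcess(neuron_ids=(in_a, in_b), kind="constant", rate=0.01)]
    return NetworkModel(neurons=neurons, synapses=synapses, inputs=inputs,
                        input_neuron_ids=(in_a, in_b),
                        metadata={"kind": "small-column", "pools": layout,
                                  "boosted": {"2->7": 5.0, "7->8": 10.0}})


# --------------------------------------------------------------------------
# readout neuron

@dataclass
class ReadoutSpec:
    """Afferent composition and weight distributions of an observer neuron.

    ``counts`` gives the number of randomly chosen presynaptic neurons
    per pool; EE and IE afferent weights are drawn from Gamma
    distributions with the given (mean, scale).
    """

    counts: Dict[str, int] = field(default_factory=lambda: {
        "L23E": 120, "L23I": 30, "L4E": 80, "L4I": 20, "L5E": 200, "L5I": 50})
    weight_ee: Tuple[float, float] = (1.2, 0.6)   # (mean nS, scale)
    weight_ie: Tuple[float, float] = (2.0, 0.8)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def attach_readout(net: NetworkModel, spec: ReadoutSpec,
                   seed: Optional[int] = None) -> NetworkModel:
    """Attach one excitatory observer neuron fed by a random subset of
    network neurons (no efferents back into the network).

    Afferent counts per pool follow ``spec.counts`` exactly; weights are
    Gamma with (mean, scale) per connection type (EE from excitatory
    pools, IE from inhibitory pools); short-term plasticity follows the
    type classes.
    """
    pools = net.metadata.get("pools")
    if pools is None:
        raise ValueError("network has no pool metadata")
    rng = np.random.default_rng(seed)
    neurons = list(net.neurons)
    neurons.append(NeuronParams(is_inhibitory=False))
    ro = len(neurons) - 1
    synapses = list(net.synapses)
    for pool, k in spec.counts.items():
        avail = list(pools[pool])
        if k > len(avail):
            raise ValueError(f"pool {pool} too small for {k} afferents")
        chosen = rng.choice(len(avail), size=k, replace=False)
        inh = pool.endswith("I")
        mean, scale = spec.weight_ie if inh else spec.weight_ee
        shape = mean / scale
        for c in chosen:
            w = float(rng.gamma(shape, scale))
            synapses.append(SynapseParams(
                pre=int(avail[c]), post=ro, weight=w, delay=1.0,
                stp=_draw_stp(rng, "I" if inh else "E", "E")))
    out = NetworkModel(
        neurons=neurons, synapses=synapses, inputs=list(net.inputs),
        threshold_modulation=net.threshold_modulation,
        input_neuron_ids=net.input_neuron_ids,
        metadata={**net.metadata, "readout_id": ro},
    )
    return out
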