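"""Time-stepped simulation of stochastic spiking networks.

The simulator advances the network on a regular grid of width ``dt``.
In each step every non-refractory neuron fires with probability
``1 - exp(-r(V) * dt)`` where ``r`` is the escape-noise hazard of its
membrane potential; at most one spike per neuron per step by
construction.  Spikes decided in step ``k`` are stamped at the end of
the step, ``t = (k+1) * dt``, and a synapse with delay ``m * dt``
affects the postsynaptic potential from step ``k + m`` on.  A neuron
that spikes is absolutely refractory for ``refractory_abs`` (minimum
interspike interval exactly ``refractory_abs``) and its membrane is
then reset to the resting potential.

Two synapse models are supported:

- ``conductance-exp``: each presynaptic spike increments an exponentially
  decaying conductance (time constants ``tau_e`` / ``tau_i``); the
  membrane integrates leak + synaptic conductances by exponential Euler.
- ``current-rect``: each spike adds a rectangular pulse (amplitude in mV,
  length ``pulse_length``) directly to the potential seen by the hazard
  function.  Networks built only from such synapses have piecewise-
  constant potentials, so the discrete-time simulation is exact up to the
  quantization of pulse boundaries to the grid.

Randomness: one ``numpy.random.Generator`` per run; each step consumes
exactly one uniform array of length ``n_neurons`` for the spike
decisions (plus occasional draws for stochastic release and
Markov-modulated inputs), so runs are bit-reproducible given
``(net, duration, dt, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .network import InputProcess, NetworkModel, SpikeRecord

__all__ = ["SimState", "run", "step", "prepare_initial_state", "RunResult"]


# --------------------------------------------------------------------------
# compiled (array-form) network

class _CompiledNet:
    """Array representation of a NetworkModel for a fixed dt."""

    def __init__(self, net: NetworkModel, dt: float):
        net.validate(dt=dt)
        self.dt = dt
        n = net.n_neurons
        self.n = n
        g = lambda attr: np.array([getattr(p, attr) for p in net.neurons], float)
        self.gL = g("leak_conductance")
        self.C_pF = 1000.0 * g("membrane_capacitance")   # pF so pA/pF = mV/ms
        self.EL = g("resting_potential")
        self.Eexc = g("reversal_exc")
        self.Einh = g("reversal_inh")
        self.r0 = g("hazard_base_rate")
        self.VT = g("hazard_threshold")
        self.dV = g("hazard_slope")
        self.rmax = g("rate_cap")
        self.bias_pA = 1000.0 * g("bias_current")
        self.bias_V = g("bias_potential")
        self.is_inh = np.array([p.is_inhibitory for p in net.neurons], bool)
        # refractory: a spike in step k blocks steps k+1 .. k+rho-1
        self.refr_steps = np.array(
            [int(round(p.refractory_abs / dt)) for p in net.neurons], np.int64)
        self.x_cap = np.log(self.rmax / self.r0)

        self.is_input = np.zeros(n, bool)
        self.is_input[list(net.input_neuron_ids)] = True

        # synapses in CSR order by presynaptic neuron
        syns = sorted(range(len(net.synapses)), key=lambda i: net.synapses[i].pre)
        self.syn_order = syns
        pre = np.array([net.synapses[i].pre for i in syns], np.int64)
        self.indptr = np.searchsorted(pre, np.arange(n + 1))
        self.post = np.array([net.synapses[i].post for i in syns], np.int64)
        self.w = np.array([net.synapses[i].weight for i in syns], float)
        self.delay_steps = np.array(
            [max(1, int(round(net.synapses[i].delay / dt))) for i in syns], np.int64)
        self.is_rect = np.array(
            [net.synapses[i].kind == "current-rect" for i in syns], bool)
        self.pulse_steps = np.array(
            [max(1, int(round(net.synapses[i].pulse_length / dt)))
             if net.synapses[i].kind == "current-rect" else 0
             for i in syns], np.int64)
        self.release_p = np.array(
            [net.synapses[i].release_probability for i in syns], float)
        self.any_release_noise = bool(np.any(self.release_p < 1.0))
        # signed rect amplitude (sign from presynaptic type)
        sign = np.where(self.is_inh[pre], -1.0, 1.0)
        self.w_rect = np.where(self.is_rect, sign * self.w, 0.0)
        # conductance channel: 0 = exc, 1 = inh
        self.chan = np.where(self.is_inh[pre], 1, 0)

        stp_list = [net.synapses[i].stp for i in syns]
        self.has_stp = np.array([s is not None for s in stp_list], bool)
        self.any_stp = bool(np.any(self.has_stp))
        self.U = np.array([s.U if s else 1.0 for s in stp_list], float)
        self.Dstp = np.array([s.D if s else 1.0 for s in stp_list], float)
        self.Fstp = np.array([s.F if s else 1.0 for s in stp_list], float)

        self.any_cond = bool(np.any(~self.is_rect))
        self.any_rect = bool(np.any(self.is_rect))
        self.n_syn = len(syns)

        self.buf_len = int(np.max(self.delay_steps + self.pulse_steps)) + 2 \
            if self.n_syn else 2

        # per-neuron constant part of the hazard potential
        self.V_base_offset = self.bias_V.copy()
        self.tmod = net.threshold_modulation
        self.inputs = list(net.inputs)
        # precompute constant input hazards
        self._const_p = None

    def const_input_p(self) -> np.ndarray:
        """Per-neuron spike probability per step for constant-rate inputs."""
        if self._const_p is None:
            p = np.zeros(self.n)
            for ip in self.inputs:
                if ip.kind == "constant":
                    ids = np.array(ip.neuron_ids, np.int64)
                    if ip.per_neuron_rates is not None:
                        rates = np.asarray(ip.per_neuron_rates, float)
                    else:
                        rates = np.full(ids.size, ip.rate)
                    p[ids] = -np.expm1(-rates * self.dt)
            self._const_p = p
        return self._const_p


def _compiled(net: NetworkModel, dt: float) -> _CompiledNet:
    cache = getattr(net, "_compiled_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(net, "_compiled_cache", cache)
    key = round(dt, 12)
    if key not in cache:
        cache[key] = _CompiledNet(net, dt)
    return cache[key]


# --------------------------------------------------------------------------
# simulation state

@dataclass
class SimState:
    """Full mutable state of a simulation at one grid time."""

    clock: float
    V: np.ndarray
    g_e: np.ndarray
    g_i: np.ndarray
    rect_level: np.ndarray
    refr_count: np.ndarray          # steps remaining blocked
    stp_u: np.ndarray
    stp_R: np.ndarray
    stp_tlast: np.ndarray           # nan before first presynaptic spike
    ge_delta: np.ndarray            # circular delivery buffers (buf_len, n)
    gi_delta: np.ndarray
    rect_delta: np.ndarray
    buf_pos: int
    rng: np.random.Generator
    mod_states: dict = field(default_factory=dict)   # input idx -> chain state
    step_index: int = 0

    def copy(self) -> "SimState":
        import copy as _copy
        new = SimState(
            clock=self.clock, V=self.V.copy(), g_e=self.g_e.copy(),
            g_i=self.g_i.copy(), rect_level=self.rect_level.copy(),
            refr_count=self.refr_count.copy(), stp_u=self.stp_u.copy(),
            stp_R=self.stp_R.copy(), stp_tlast=self.stp_tlast.copy(),
            ge_delta=self.ge_delta.copy(), gi_delta=self.gi_delta.copy(),
            rect_delta=self.rect_delta.copy(), buf_pos=self.buf_pos,
            rng=_copy.deepcopy(self.rng), mod_states=dict(self.mod_states),
            step_index=self.step_index,
        )
        return new


def _fresh_state(cn: _CompiledNet, rng: np.random.Generator,
                 random_init: bool = True) -> SimState:
    n = cn.n
    has_membrane = cn.any_cond or bool(np.any(cn.bias_pA))
    if random_init and has_membrane:
        # initial potentials uniform between rest and soft threshold
        V = rng.uniform(cn.EL, np.maximum(cn.EL, cn.VT))
    else:
        # point-process (rectangular-pulse) networks have no free
        # membrane dynamics: the potential is pinned to rest + pulses
        V = cn.EL.copy()
    return SimState(
        clock=0.0, V=V, g_e=np.zeros(n), g_i=np.zeros(n),
        rect_level=np.zeros(n), refr_count=np.zeros(n, np.int64),
        stp_u=np.full(cn.n_syn, np.nan), stp_R=np.full(cn.n_syn, np.nan),
        stp_tlast=np.full(cn.n_syn, np.nan),
        ge_delta=np.zeros((cn.buf_len, n)), gi_delta=np.zeros((cn.buf_len, n)),
        rect_delta=np.zeros((cn.buf_len, n)), buf_pos=0, rng=rng,
    )


# --------------------------------------------------------------------------
# stepping

def _input_p(cn: _CompiledNet, st: SimState, t: float) -> Optional[np.ndarray]:
    """Per-step spike probability for input neurons, or None if no inputs."""
    if not cn.inputs:
        return None
    p = cn.const_input_p().copy() if any(
        ip.kind == "constant" for ip in cn.inputs) else np.zeros(cn.n)
    for idx, ip in enumerate(cn.inputs):
        if ip.kind == "constant":
            continue
        ids = np.array(ip.neuron_ids, np.int64)
        if ip.kind == "periodic":
            lam = max(0.0, ip.rate_fn(t % ip.period))
            p[ids] = -math.expm1(-lam * cn.dt)
        elif ip.kind == "schedule":
            lam = ip.rate_at(t)
            p[ids] = -math.expm1(-lam * cn.dt)
        elif ip.kind == "markov-modulated":
            mod = ip.modulator
            dwell = mod["dwell"]
            state = st.mod_states.get(idx, 0)
            # transition when crossing a dwell boundary
            k_now = int(t / dwell)
            k_prev = st.mod_states.get(("k", idx), k_now)
            for _ in range(k_now - k_prev):
                probs = np.asarray(mod["transition"][state], float)
                state = int(st.rng.choice(len(probs), p=probs / probs.sum()))
            st.mod_states[idx] = state
            st.mod_states[("k", idx)] = k_now
            lam = mod["rates"][state]
            p[ids] = -math.expm1(-lam * cn.dt)
    return p


def _advance(cn: _CompiledNet, st: SimState,
             record_potentials: bool = False):
    """Advance one step; returns indices of neurons that spiked."""
    dt = cn.dt
    t = st.clock
    pos = st.buf_pos

    # 1. deliver due synaptic events
    if cn.any_rect:
        st.rect_level += st.rect_delta[pos]
        st.rect_delta[pos] = 0.0
    if cn.any_cond:
        st.g_e += st.ge_delta[pos]
        st.ge_delta[pos] = 0.0
        st.g_i += st.gi_delta[pos]
        st.gi_delta[pos] = 0.0

    # 2. hazard potential and spike probabilities
    V_eff = st.V + st.rect_level + cn.V_base_offset
    offset = cn.tmod.offset(t) if cn.tmod is not None else 0.0
    x = (V_eff - (cn.VT + offset)) / cn.dV
    r = cn.r0 * np.exp(np.minimum(x, cn.x_cap))
    p = -np.expm1(-r * dt)
    refractory = st.refr_count > 0
    p[refractory] = 0.0
    ip = _input_p(cn, st, t)
    if ip is not None:
        p[cn.is_input] = ip[cn.is_input]

    # 3. spike decisions (one uniform array per step, always)
    u = st.rng.random(cn.n)
    spiked = u < p
    spike_idx = np.nonzero(spiked)[0]

    # 4. refractoriness bookkeeping and reset
    st.refr_count[~refractory] = 0
    st.refr_count[refractory] -= 1
    ended = refractory & (st.refr_count == 0)
    if np.any(ended):
        st.V[ended] = cn.EL[ended]     # reset to rest after refractory period
    if spike_idx.size:
        st.refr_count[spike_idx] = np.maximum(cn.refr_steps[spike_idx] - 1, 0)
        imm = spike_idx[cn.refr_steps[spike_idx] <= 1]
        if imm.size:
            st.V[imm] = cn.EL[imm]

    # 5. schedule deliveries from this step's spikes
    if spike_idx.size and cn.n_syn:
        parts = [np.arange(cn.indptr[i], cn.indptr[i + 1]) for i in spike_idx
                 if cn.indptr[i + 1] > cn.indptr[i]]
        if parts:
            sidx = np.concatenate(parts)
            amp_scale = np.ones(sidx.size)
            if cn.any_stp:
                m = cn.has_stp[sidx]
                if np.any(m):
                    j = sidx[m]
                    first = np.isnan(cn_tlast := st.stp_tlast[j])
                    delta = (t + dt) - cn_tlast
                    eF = np.exp(-delta / cn.Fstp[j])
                    eD = np.exp(-delta / cn.Dstp[j])
                    u_new = np.where(first, cn.U[j],
                                     cn.U[j] + st.stp_u[j] * (1 - cn.U[j]) * eF)
                    R_new = np.where(
                        first, 1.0,
                        1.0 + (st.stp_R[j] * (1 - st.stp_u[j]) - 1.0) * eD)
                    st.stp_u[j] = u_new
                    st.stp_R[j] = R_new
                    st.stp_tlast[j] = t + dt
                    amp_scale[m] = u_new * R_new
            if cn.any_release_noise:
                noisy = cn.release_p[sidx] < 1.0
                if np.any(noisy):
                    keep = st.rng.random(int(noisy.sum())) < cn.release_p[sidx][noisy]
                    amp_scale[noisy] *= keep
            slot_on = (pos + cn.delay_steps[sidx]) % cn.buf_len
            rect = cn.is_rect[sidx]
            if np.any(rect):
                ri = sidx[rect]
                amp = cn.w_rect[ri] * amp_scale[rect]
                np.add.at(st.rect_delta, (slot_on[rect], cn.post[ri]), amp)
                slot_off = (pos + cn.delay_steps[ri] + cn.pulse_steps[ri]) % cn.buf_len
                np.add.at(st.rect_delta, (slot_off, cn.post[ri]), -amp)
            if np.any(~rect):
                ci = sidx[~rect]
                amp = cn.w[ci] * amp_scale[~rect]
                exc = cn.chan[ci] == 0
                if np.any(exc):
                    np.add.at(st.ge_delta, (slot_on[~rect][exc], cn.post[ci][exc]),
                              amp[exc])
                if np.any(~exc):
                    np.add.at(st.gi_delta, (slot_on[~rect][~exc], cn.post[ci][~exc]),
                              amp[~exc])

    # 6. membrane integration (exponential Euler) for conductance dynamics
    if cn.any_cond or np.any(cn.bias_pA):
        g_tot = cn.gL + st.g_e + st.g_i
        V_inf = (cn.gL * cn.EL + st.g_e * cn.Eexc + st.g_i * cn.Einh
                 + cn.bias_pA) / g_tot
        decay = np.exp(-dt * g_tot / cn.C_pF)
        newV = V_inf + (st.V - V_inf) * decay
        # refractory neurons hold; they are reset to EL at refractory end
        active = st.refr_count == 0
        st.V[active] = newV[active]
        st.g_e *= math.exp(-dt / cn._tau_e)
        st.g_i *= math.exp(-dt / cn._tau_i)

    st.buf_pos = (pos + 1) % cn.buf_len
    st.clock = t + dt
    st.step_index += 1
    if record_potentials:
        return spike_idx, V_eff
    return spike_idx, None


# --------------------------------------------------------------------------
# fast path for purely rectangular-pulse networks (no conductances, no
# inputs, no STP): the membrane is piecewise constant, so the whole step
# reduces to integer bookkeeping plus one hazard evaluation per neuron.
# Uniform variates are pre-generated from the same generator in the same
# order as the generic path, so both paths produce bit-identical runs.

try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except Exception:             # pragma: no cover - numba is an optional accel
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@_njit(cache=True)
def _rect_kernel(U, x_base, inv_dV, r0, xcap, dt,
                 refr_steps, refr, rect_level, rect_delta, pos0,
                 indptr, post, w_rect, delay_steps, off_steps,
                 out_step, out_id):   # pragma: no cover - exercised via run()
    n_steps, n = U.shape
    buf_len = rect_delta.shape[0]
    n_out = 0
    for k in range(n_steps):
        pos = (pos0 + k) % buf_len
        for i in range(n):
            rect_level[i] += rect_delta[pos, i]
            rect_delta[pos, i] = 0.0
        for i in range(n):
            if refr[i] > 0:
                refr[i] -= 1
                continue
            x = x_base[i] + rect_level[i] * inv_dV[i]
            if x > xcap[i]:
                x = xcap[i]
            p = 1.0 - np.exp(-r0[i] * np.exp(x) * dt)
            if U[k, i] < p:
                if n_out >= out_step.size:
                    return -1
                out_step[n_out] = k
                out_id[n_out] = i
                n_out += 1
                if refr_steps[i] > 1:
                    refr[i] = refr_steps[i] - 1
                for s in range(indptr[i], indptr[i + 1]):
                    a = w_rect[s]
                    rect_delta[(pos + delay_steps[s]) % buf_len, post[s]] += a
                    rect_delta[(pos + off_steps[s]) % buf_len, post[s]] -= a
    return n_out


def _rect_fast_possible(cn: _CompiledNet) -> bool:
    return (_HAVE_NUMBA and not cn.any_cond and not cn.any_stp
            and not cn.any_release_noise and not cn.inputs
            and cn.tmod is None and not np.any(cn.bias_pA))


def _run_rect_fast(cn: _CompiledNet, st: SimState, n_steps: int,
                   chunk: int = 512):
    """Advance ``n_steps`` via the jitted kernel; returns (ids, steps)."""
    off = cn.delay_steps + cn.pulse_steps
    x_base = (cn.EL + cn.V_base_offset + st.V - cn.EL - cn.VT) / cn.dV
    # st.V is constant (= EL) on this path but folded in for safety
    out_ids, out_steps = [], []
    done = 0
    while done < n_steps:
        m = min(chunk, n_steps - done)
        U = st.rng.random((m, cn.n))
        cap = max(4096, m * 128)
        while True:
            o_step = np.empty(cap, np.int64)
            o_id = np.empty(cap, np.int64)
            refr0 = st.refr_count.copy()
            level0 = st.rect_level.copy()
            delta0 = st.rect_delta.copy()
            n_out = _rect_kernel(
                U, x_base, 1.0 / cn.dV, cn.r0, cn.x_cap,
                cn.dt, cn.refr_steps, st.refr_count, st.rect_level,
                st.rect_delta, st.buf_pos, cn.indptr, cn.post, cn.w_rect,
                cn.delay_steps, off, o_step, o_id)
            if n_out >= 0:
                break
            # buffer overflow: restore state and retry with more room
            st.refr_count, st.rect_level, st.rect_delta = refr0, level0, delta0
            cap *= 4
        out_steps.append(st.step_index + o_step[:n_out] + 1)
        out_ids.append(o_id[:n_out])
        st.buf_pos = (st.buf_pos + m) % cn.buf_len
        st.step_index += m
        st.clock += m * cn.dt
        done += m
    return np.concatenate(out_ids), np.concatenate(out_steps)


def step(state: SimState, net: NetworkModel, dt: float) -> np.ndarray:
    """Advance ``state`` by one step of width ``dt``; returns spiking ids.

    The state's own rng stream is consumed.  ``dt`` must match the
    state's grid and not exceed the smallest synaptic delay.
    """
    cn = _compiled(net, dt)
    _ensure_tau(cn)
    spike_idx, _ = _advance(cn, state)
    return spike_idx


def _ensure_tau(cn: _CompiledNet, tau_e: float = 5.0, tau_i: float = 10.0):
    if not hasattr(cn, "_tau_e"):
        cn._tau_e = tau_e
        cn._tau_i = tau_i


@dataclass
class RunResult:
    spikes: SpikeRecord
    state: SimState
    potentials: Optional[np.ndarray] = None    # (n_steps, n) if recorded
    potential_times: Optional[np.ndarray] = None


def run(net: NetworkModel, duration: float, dt: float = 0.1,
        seed: Optional[int] = None, record: str = "spikes",
        initial_state: Optional[SimState] = None,
        tau_e: float = 5.0, tau_i: float = 10.0,
        random_init: bool = True) -> RunResult:
    """Simulate ``net`` for ``duration`` ms on a grid of width ``dt`` ms.

    Deterministic given ``(net, duration, dt, seed)``.  If
    ``initial_state`` is given, simulation continues from it (its rng
    stream is used and ``seed`` must be None).  ``record`` is
    ``"spikes"`` or ``"spikes+potentials"``.  Spike times are reported
    relative to the state's starting clock.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    cn = _compiled(net, dt)
    _ensure_tau(cn, tau_e, tau_i)
    cn._tau_e, cn._tau_i = tau_e, tau_i
    if initial_state is not None:
        if seed is not None:
            raise ValueError("pass either seed or initial_state, not both")
        st = initial_state
    else:
        rng = np.random.default_rng(seed)
        st = _fresh_state(cn, rng, random_init=random_init)
    want_V = record == "spikes+potentials"
    n_steps = int(round(duration / dt))
    t0 = st.clock
    if not want_V and _rect_fast_possible(cn):
        start_step = st.step_index
        ids_arr, steps_arr = _run_rect_fast(cn, st, n_steps)
        rec = SpikeRecord(ids_arr, (steps_arr - start_step) * dt)
        return RunResult(spikes=rec, state=st)
    ids, ts = [], []
    traces = np.empty((n_steps, cn.n)) if want_V else None
    for k in range(n_steps):
        spike_idx, V_eff = _advance(cn, st, record_potentials=want_V)
        if want_V:
            traces[k] = V_eff
        if spike_idx.size:
            ids.append(spike_idx)
            ts.append(np.full(spike_idx.size, st.clock))  # stamped end-of-step
    if ids:
        rec = SpikeRecord(np.concatenate(ids), np.concatenate(ts) - t0)
    else:
        rec = SpikeRecord()
    times = t0 + dt * (np.arange(n_steps) + 1) - t0 if want_V else None
    return RunResult(spikes=rec, state=st, potentials=traces,
                     potential_times=times)


def prepare_initial_state(net: NetworkModel,
                          preparatory_inputs: Sequence[InputProcess],
                          prep_duration: float, prep_seed: int,
                          main_seed: int, dt: float = 0.1,
                          state_window: float = 0.0,
                          tau_e: float = 5.0, tau_i: float = 10.0):
    """Run a preparatory phase and return the state at t = 0.

    The network is driven for ``prep_duration`` ms by
    ``preparatory_inputs`` (replacing the model's own input processes)
    using ``prep_seed``; then the rng is re-seeded with ``main_seed`` so
    that repeated calls with equal ``prep_seed`` but different
    ``main_seed`` reproduce the identical initial spike history with
    divergent futures.

    Returns ``(state, prep_record)`` where the record's times lie in
    ``[-prep_duration, 0]``.
    """
    if prep_duration < state_window:
        raise ValueError(
            "prep_duration must cover at least one state window")
    prep_net = NetworkModel(
        neurons=list(net.neurons), synapses=list(net.synapses),
        inputs=list(preparatory_inputs),
        threshold_modulation=net.threshold_modulation,
        input_neuron_ids=net.input_neuron_ids,
        metadata=dict(net.metadata),
    )
    res = run(prep_net, prep_duration, dt=dt, seed=prep_seed,
              tau_e=tau_e, tau_i=tau_i)
    st = res.state
    st.clock = 0.0
    st.step_index = 0
    st.rng = np.random.default_rng(main_seed)
    prep_rec = res.spikes.shifted(-prep_duration)
    return st, prep_rec
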