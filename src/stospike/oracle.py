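"""Brute-force ergodicity verification on tiny discretized networks.

For networks of at most 3 neurons the discrete-time dynamics over binary
spike/silence histories of depth k (bins of width dt) can be enumerated
exactly: the state space is all 2**(n*k) histories and the one-step
kernel is a row-stochastic matrix.  On this enumerable surface the
package verifies, rather than assumes, the contraction property that
underlies ergodicity of stochastic spiking networks:

- the return probability to the resting (all-silent) state within one
  memory window is bounded below by ``alpha > 0`` (and by the generic
  no-spike bound ``exp(-Lambda * tau)`` with ``Lambda`` the summed rate
  caps), and
- one memory window of dynamics contracts the total-variation distance
  between any two state distributions by at least ``(1 - alpha)``.

Total variation here is the *un-halved* L1 mass ``sum |mu - nu|`` (so
disjoint point masses are at distance 2).

For networks with rectangular-pulse synapses the kernel agrees exactly
with the time-stepped simulator; conductance-based synapses are
discretized by replaying exponential PSP kernels over the history bins
(a quasi-stationary approximation of the continuous membrane).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .network import NetworkModel

__all__ = [
    "DiscretizedChain", "build_kernel", "tv_distance",
    "verify_contraction", "stationary_distribution", "phase_stationary",
]

_MAX_STATES = 2 ** 12


@dataclass
class DiscretizedChain:
    """Exact transition kernel over binary spike histories.

    State encoding: bit ``i*k + j`` set iff neuron i spiked in step
    ``t - (j+1)``.  The resting state (index 0) is the all-silent
    history.
    """

    n_neurons: int
    history_depth: int
    dt: float
    P: np.ndarray
    rate_bound: Optional[float] = None    # Lambda = sum of rate caps, 1/ms
    resting_index: int = 0

    def __post_init__(self) -> None:
        rows = self.P.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-12):
            raise ValueError("kernel rows must sum to 1")

    @property
    def n_states(self) -> int:
        return self.P.shape[0]


def _spike_probs(cn, state_bits: np.ndarray, k: int, dt: float,
                 tau_e: float, tau_i: float) -> np.ndarray:
    """Per-neuron spike probability given the history encoded in
    ``state_bits`` (shape (n, k); column j = spiked in step t-(j+1))."""
    n = cn.n
    p = np.zeros(n)
    # synaptic potential / conductances replayed from the history bins
    rect = np.zeros(n)
    g_e = np.zeros(n)
    g_i = np.zeros(n)
    for s in range(cn.n_syn):
        pre, post = int(np.searchsorted(cn.indptr, s, side="right") - 1), cn.post[s]
        d = cn.delay_steps[s]
        if cn.is_rect[s]:
            # active if pre spiked within [d, d + pulse - 1] steps ago
            for age in range(d, min(d + cn.pulse_steps[s], k + 1)):
                if age >= 1 and state_bits[pre, age - 1]:
                    rect[post] += cn.w_rect[s]
        else:
            for age in range(d, k + 1):
                if age >= 1 and state_bits[pre, age - 1]:
                    decay = math.exp(-(age - d) * dt /
                                     (tau_i if cn.chan[s] else tau_e))
                    if cn.chan[s]:
                        g_i[post] += cn.w[s] * decay
                    else:
                        g_e[post] += cn.w[s] * decay
    g_tot = cn.gL + g_e + g_i
    V = (cn.gL * cn.EL + g_e * cn.Eexc + g_i * cn.Einh + cn.bias_pA) / g_tot
    V_eff = V + rect + cn.V_base_offset
    x = (V_eff - cn.VT) / cn.dV
    r = cn.r0 * np.exp(np.minimum(x, cn.x_cap))
    p = -np.expm1(-r * dt)
    # refractoriness: spiked within the last (rho - 1) steps blocks firing
    for i in range(n):
        rho = int(cn.refr_steps[i])
        if rho > 1 and np.any(state_bits[i, :min(rho - 1, k)]):
            p[i] = 0.0
    return p


def build_kernel(net: NetworkModel, dt: float, k: int,
                 tau_e: float = 5.0, tau_i: float = 10.0) -> DiscretizedChain:
    """Enumerate the exact one-step kernel of ``net`` discretized to
    history depth ``k`` bins of width ``dt``.

    Requires the state space 2**(n*k) to stay at or below 2**12.
    Synaptic delays and pulse lengths must fit within the k bins for
    the history to be a sufficient (Markov) state.
    """
    from .simulate import _compiled
    n = net.n_neurons
    n_states = 2 ** (n * k)
    if n_states > _MAX_STATES:
        raise ValueError(f"state space 2**({n}*{k}) exceeds 2**12")
    cn = _compiled(net, dt)
    if cn.n_syn:
        reach = cn.delay_steps + np.where(cn.is_rect, cn.pulse_steps - 1, 0)
        if int(np.max(reach)) > k:
            raise ValueError("synaptic memory exceeds history depth k")
    if int(np.max(cn.refr_steps, initial=0)) - 1 > k:
        raise ValueError("refractory memory exceeds history depth k")

    P = np.zeros((n_states, n_states))
    combos = [(tuple((c >> i) & 1 for i in range(n))) for c in range(2 ** n)]
    for s in range(n_states):
        bits = np.array([[(s >> (i * k + j)) & 1 for j in range(k)]
                         for i in range(n)], dtype=np.int64)
        p = _spike_probs(cn, bits, k, dt, tau_e, tau_i)
        # shift history by one bin
        shifted = np.zeros_like(bits)
        if k > 1:
            shifted[:, 1:] = bits[:, :-1]
        base = sum(int(shifted[i, j]) << (i * k + j)
                   for i in range(n) for j in range(k))
        for combo in combos:
            prob = 1.0
            tgt = base
            for i, b in enumerate(combo):
                prob *= p[i] if b else (1.0 - p[i])
                if b:
                    tgt |= 1 << (i * k)
            P[s, tgt] += prob
    rate_bound = float(np.sum(cn.rmax[~cn.is_input]))
    return DiscretizedChain(n_neurons=n, history_depth=k, dt=dt, P=P,
                            rate_bound=rate_bound)


def tv_distance(mu: np.ndarray, nu: np.ndarray) -> float:
    """Un-halved total variation distance ``sum |mu_i - nu_i|``."""
    mu = np.asarray(mu, float)
    nu = np.asarray(nu, float)
    if mu.shape != nu.shape:
        raise ValueError("distributions must share their support")
    return float(np.sum(np.abs(mu - nu)))


@dataclass
class ContractionReport:
    alpha: float
    tau: float
    worst_ratio: float
    n_pairs: int
    no_spike_bound: Optional[float] = None
    satisfied: bool = True


def verify_contraction(chain: DiscretizedChain, steps_per_tau: int,
                       pairs: Sequence[Tuple[np.ndarray, np.ndarray]],
                       tol: float = 1e-10) -> ContractionReport:
    """Verify the contraction property over one memory window.

    Computes ``alpha = min_s P^m(s -> resting)`` for ``m =
    steps_per_tau`` and checks, for every supplied pair of initial
    distributions, that

        tv(mu P^m, nu P^m) <= (1 - alpha) * tv(mu, nu) + tol .

    Also checks ``alpha >= exp(-Lambda * tau)`` (the probability that no
    neuron spikes during the window, which lands the chain in the
    resting state) when the rate bound is available.  Raises if
    ``alpha == 0``: such a chain is insufficiently stochastic and the
    ergodicity guarantee does not apply (e.g. deterministic dynamics).
    """
    if steps_per_tau < chain.history_depth:
        raise ValueError("steps_per_tau must cover one full memory window")
    Pm = np.linalg.matrix_power(chain.P, steps_per_tau)
    alpha = float(np.min(Pm[:, chain.resting_index]))
    if alpha <= 0.0:
        raise ValueError(
            "alpha = 0: chain is insufficiently stochastic "
            "(no uniform return probability to the resting state)")
    tau = steps_per_tau * chain.dt
    bound = None
    if chain.rate_bound is not None:
        bound = math.exp(-chain.rate_bound * tau)
        if alpha + 1e-12 < bound:
            raise AssertionError(
                f"alpha={alpha} below the no-spike bound exp(-Lambda*tau)={bound}")
    worst = 0.0
    for mu, nu in pairs:
        d0 = tv_distance(mu, nu)
        d1 = tv_distance(mu @ Pm, nu @ Pm)
        if d1 > (1.0 - alpha) * d0 + tol:
            raise AssertionError(
                f"contraction violated: tv {d0} -> {d1}, alpha={alpha}")
        if d0 > 0:
            worst = max(worst, d1 / d0)
    return ContractionReport(alpha=alpha, tau=tau, worst_ratio=worst,
                             n_pairs=len(pairs), no_spike_bound=bound)


def stationary_distribution(chain: DiscretizedChain, tol: float = 1e-12,
                            max_iter: int = 200000) -> np.ndarray:
    """Unique stationary distribution by power iteration.

    Iterates from the uniform distribution until successive iterates
    differ by less than ``tol`` in (un-halved) total variation; the
    contraction property guarantees geometric convergence.
    """
    n = chain.n_states
    mu = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = mu @ chain.P
        if tv_distance(nxt, mu) < tol:
            nxt /= nxt.sum()
            return nxt
        mu = nxt
    raise RuntimeError("power iteration did not converge")


def phase_stationary(phase_kernels: Sequence[np.ndarray],
                     tol: float = 1e-12) -> List[np.ndarray]:
    """Phase-specific stationary distributions under periodic dynamics.

    Given per-phase kernels P_0 ... P_{L-1} (one per phase bin of the
    input period), returns [p(phi_0), ..., p(phi_{L-1})] where p(phi_l)
    is the fixed point of the cyclic product P_l P_{l+1} ... P_{l-1};
    consecutive phases satisfy p(phi_{l+1}) = p(phi_l) P_l.
    """
    L = len(phase_kernels)
    if L == 0:
        raise ValueError("need at least one phase kernel")
    n = phase_kernels[0].shape[0]
    for P in phase_kernels:
        if P.shape != (n, n):
            raise ValueError("phase kernels must share one state space")
        if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("phase kernels must be row-stochastic")
    # fixed point of the full-cycle kernel starting at phase 0
    cycle = np.eye(n)
    for P in phase_kernels:
        cycle = cycle @ P
    mu = np.full(n, 1.0 / n)
    for _ in range(200000):
        nxt = mu @ cycle
        if tv_distance(nxt, mu) < tol:
            mu = nxt / nxt.sum()
            break
        mu = nxt
    else:
        raise RuntimeError("cyclic power iteration did not converge")
    out = [mu]
    for l in range(L - 1):
        out.append(out[-1] @ phase_kernels[l])
    return out
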