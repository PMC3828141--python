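"""Exponential escape-rate (hazard) function.

The instantaneous firing rate of an escape-noise neuron is

    r(V) = min( r0 * exp((V - V_T) / dV), r_max )

where V_T is the soft threshold, dV the softness of the threshold, r0
the rate at threshold, and r_max a hard cap enforcing the bounded-rate
assumption required for ergodicity (the probability of *no* spike in any
finite window must be bounded away from zero).
"""

from __future__ import annotations

import math

import numpy as np

from .network import NeuronParams

__all__ = ["hazard_rate", "hazard_rate_arr"]


def hazard_rate(V: float, p: NeuronParams, threshold_offset: float = 0.0) -> float:
    """Instantaneous firing rate (1/ms) at membrane potential ``V`` (mV).

    ``threshold_offset`` shifts the soft threshold V_T (used for global
    periodic threshold modulation).  Monotone nondecreasing in V; capped
    at ``p.rate_cap``.
    """
    if not math.isfinite(V):
        raise ValueError(f"non-finite membrane potential {V!r}")
    x = (V - (p.hazard_threshold + threshold_offset)) / p.hazard_slope
    # exponent clipped before exp to avoid overflow; the cap binds anyway
    cap_x = math.log(p.rate_cap / p.hazard_base_rate)
    if x >= cap_x:
        return p.rate_cap
    return p.hazard_base_rate * math.exp(x)


def hazard_rate_arr(V: np.ndarray, r0: np.ndarray, V_T: np.ndarray,
                    dV: np.ndarray, r_max: np.ndarray,
                    threshold_offset: float = 0.0) -> np.ndarray:
    """Vectorized hazard over per-neuron parameter arrays."""
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite membrane potential")
    x = (V - (V_T + threshold_offset)) / dV
    r = r0 * np.exp(np.minimum(x, np.log(r_max / r0)))
    return np.minimum(r, r_max)
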