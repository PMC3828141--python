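"""Short-term synaptic plasticity (depression + facilitation).

The amplitude of the k-th spike in a presynaptic train with interspike
intervals Delta_k is A_k = w * u_k * R_k, where the hidden utilization
u and recovery R variables follow the standard recurrences

    u_1 = U,  R_1 = 1
    u_{k+1} = U + u_k (1 - U) exp(-Delta_k / F)
    R_{k+1} = 1 + (R_k (1 - u_k) - 1) exp(-Delta_k / D)

U: utilization of efficacy by the first spike after rest; D: recovery
(depression) time constant; F: facilitation time constant, all per
synapse (or per presynaptic neuron and connection type).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

__all__ = ["stp_amplitudes", "STPState"]


@dataclass
class STPState:
    """Running state of one dynamic synapse (between presynaptic spikes)."""

    u: float
    R: float
    t_last_pre: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.u <= 1):
            raise ValueError("u must be in (0, 1]")
        if not (0 <= self.R <= 1):
            raise ValueError("R must be in [0, 1]")


def stp_amplitudes(w: float, U: float, D: float, F: float,
                   intervals: Sequence[float]) -> List[float]:
    """Amplitudes A_k for a train whose interspike intervals are ``intervals``.

    ``intervals[k]`` is the gap Delta_k between spike k+1 and spike k+2
    (0-based), so the returned list has ``len(intervals) + 1`` entries:
    one amplitude per spike, starting from a fully recovered synapse.
    """
    if not (0 < U <= 1):
        raise ValueError("U must be in (0, 1]")
    if not (D > 0 and F > 0):
        raise ValueError("D and F must be > 0")
    for d in intervals:
        if not (d > 0):
            raise ValueError("interspike intervals must be positive")
    import math

    u, R = U, 1.0
    amps = [w * u * R]
    for delta in intervals:
        eF = math.exp(-delta / F)
        eD = math.exp(-delta / D)
        u_next = U + u * (1.0 - U) * eF
        R_next = 1.0 + (R * (1.0 - u) - 1.0) * eD
        u, R = u_next, R_next
        amps.append(w * u * R)
    return amps
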