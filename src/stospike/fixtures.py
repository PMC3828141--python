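"""Synthetic spike-record fixtures with known statistical structure.

These generators build spike records whose state statistics are known
by construction (target occupancies, periodic gating, attractor
handovers, independent Poisson chains), for use in tests of the state
and diagnostics modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .network import SpikeRecord

__all__ = ["FixtureSpec", "generate_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of a synthetic spike record.

    kinds:

    - ``poisson-chains``: ``n_neurons`` independent Poisson trains at
      ``rates`` (1/ms) for ``duration`` ms.
    - ``two-state-occupancy``: one neuron whose activity bit (window
      ``tau``) is 1 for a fraction ``occupancy`` of the record: spikes
      are laid down in regular active blocks.
    - ``handover``: pools A and B of ``pool_size`` neurons; A is active
      until ``t_switch - gap/2``, B from ``t_switch + gap/2``; the
      constructed transition midpoint is exactly ``t_switch``.
    - ``periodic-gated``: neurons fire only during the first half of
      each cycle of length ``period``.
    """

    kind: str
    duration: float = 1000.0
    n_neurons: int = 1
    rates: tuple = (0.02,)
    occupancy: float = 0.3
    tau: float = 20.0
    pool_size: int = 4
    t_switch: float = 500.0
    gap: float = 40.0
    period: float = 100.0
    n_handover: int = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("poisson-chains", "two-state-occupancy",
                             "handover", "periodic-gated"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if not (0 <= self.occupancy <= 1):
            raise ValueError("occupancy must be in [0,1]")


def _sorted_record(ids, ts) -> SpikeRecord:
    ids = np.asarray(ids, np.int64)
    ts = np.asarray(ts, float)
    order = np.argsort(ts, kind="stable")
    return SpikeRecord(ids[order], ts[order])


def generate_fixture(spec: FixtureSpec) -> SpikeRecord:
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "poisson-chains":
        ids, ts = [], []
        for i in range(spec.n_neurons):
            rate = spec.rates[i % len(spec.rates)]
            n = rng.poisson(rate * spec.duration)
            times = np.sort(rng.uniform(0, spec.duration, size=n))
            ids.extend([i] * n)
            ts.extend(times)
        return _sorted_record(ids, ts)

    if spec.kind == "two-state-occupancy":
        # active blocks of length `tau` starting at multiples of
        # tau/occupancy: a spike at the start of each block keeps the
        # activity bit high for exactly tau, giving the target fraction
        if spec.occupancy == 0:
            return SpikeRecord()
        block = spec.tau / spec.occupancy
        starts = np.arange(0.0, spec.duration, block)
        return _sorted_record(np.zeros(starts.size), starts)

    if spec.kind == "handover":
        ids, ts = [], []
        seg = spec.duration / spec.n_handover
        isi = spec.tau / 4
        for h in range(spec.n_handover):
            t0, t1 = h * seg, (h + 1) * seg
            tm = t0 + spec.t_switch % seg if spec.n_handover == 1 else (t0 + t1) / 2
            first, second = (0, 1) if h % 2 == 0 else (1, 0)
            for t in np.arange(t0 + isi, tm - spec.gap / 2, isi):
                for k in range(spec.pool_size):
                    ids.append(first * spec.pool_size + k)
                    ts.append(t)
            for t in np.arange(tm + spec.gap / 2, t1, isi):
                for k in range(spec.pool_size):
                    ids.append(second * spec.pool_size + k)
                    ts.append(t)
        return _sorted_record(ids, ts)

    # periodic-gated
    ids, ts = [], []
    isi = spec.tau / 4 if spec.tau else 5.0
    for i in range(spec.n_neurons):
        t = 0.0
        while t < spec.duration:
            if (t % spec.period) < spec.period / 2:
                ids.append(i)
                ts.append(t)
                t += isi
            else:
                t = (np.floor(t / spec.period) + 1) * spec.period
    return _sorted_record(ids, ts)
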