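"""Network states and empirical distributions over them.

A *simple state* at time t is the binary vector recording, per neuron,
whether it spiked within the trailing window (t - tau, t].  A *Markov
state* is the full list of recent spike times per neuron within a longer
window (t - T, t], offsets taken relative to the window start; under the
model assumptions it renders the dynamics Markovian.  Distributions over
simple states are estimated as the relative time spent in each state,
sampled on a regular grid; under periodic input the distribution is
estimated per phase of the cycle.

All windows are half-open ``(t - w, t]``: a spike exactly at the
sampling instant counts, a spike exactly at the window's left edge does
not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .network import SpikeRecord

__all__ = [
    "StateConfig", "SimpleState", "MarkovState", "EmpiricalDistribution",
    "simple_state", "markov_state", "empirical_distribution",
    "estimate_marginal", "map_readout", "phase_distribution",
    "trajectory_distribution", "detect_attractor_transitions",
]


@dataclass(frozen=True)
class StateConfig:
    """Windows and sampling grid for state extraction.

    ``markov_window`` (T) and ``simple_window`` (tau) in ms; samples are
    taken on a grid of spacing ``dt_sample``.  ``subset`` restricts the
    state to the listed neuron ids (default: all ids present must be
    given explicitly via ``n_neurons``).
    """

    simple_window: float = 20.0       # tau
    markov_window: float = 100.0      # T
    dt_sample: float = 0.1
    subset: Optional[Tuple[int, ...]] = None
    n_neurons: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 < self.simple_window <= self.markov_window):
            raise ValueError("require 0 < tau <= T")
        if not (self.dt_sample > 0):
            raise ValueError("dt_sample must be > 0")

    def ids(self) -> Tuple[int, ...]:
        if self.subset is not None:
            return tuple(self.subset)
        if self.n_neurons is None:
            raise ValueError("StateConfig needs subset or n_neurons")
        return tuple(range(self.n_neurons))


SimpleState = Tuple[int, ...]
"""Binary tuple over the configured subset (1 = spiked within tau)."""


@dataclass(frozen=True)
class MarkovState:
    """Per-neuron recent spike times, offsets in [0, T) from window start."""

    offsets: Tuple[Tuple[float, ...], ...]
    window: float

    @property
    def is_resting(self) -> bool:
        return all(len(o) == 0 for o in self.offsets)

    def restrict(self, tau: float) -> Tuple[int, ...]:
        """Binarize the trailing tau: the simple state at the same instant."""
        lo = self.window - tau
        return tuple(int(any(x > lo for x in o)) for o in self.offsets)


@dataclass
class EmpiricalDistribution:
    """Normalized frequencies over (sub)network states."""

    freq: Dict[tuple, float]
    n_samples: int
    phase: Optional[float] = None
    period: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be > 0")
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"frequencies sum to {total}, not 1")
        if any(v < 0 for v in self.freq.values()):
            raise ValueError("negative frequency")

    @property
    def support(self) -> List[tuple]:
        return list(self.freq)

    def prob(self, state: tuple) -> float:
        return self.freq.get(tuple(state), 0.0)

    def marginalize(self, keep: Sequence[int]) -> "EmpiricalDistribution":
        """Marginal over the state components at positions ``keep``."""
        out: Dict[tuple, float] = {}
        for s, f in self.freq.items():
            key = tuple(s[i] for i in keep)
            out[key] = out.get(key, 0.0) + f
        return EmpiricalDistribution(out, self.n_samples,
                                     phase=self.phase, period=self.period)


def _counts_in_windows(spikes: SpikeRecord, ids: Sequence[int],
                       t_grid: np.ndarray, tau: float) -> np.ndarray:
    """(n_ids, n_grid) matrix: spikes of id i in (t - tau, t] per grid t."""
    out = np.zeros((len(ids), t_grid.size), dtype=np.int64)
    for row, nid in enumerate(ids):
        ts = spikes.spikes_of(nid)
        if ts.size:
            hi = np.searchsorted(ts, t_grid, side="right")
            lo = np.searchsorted(ts, t_grid - tau, side="right")
            out[row] = hi - lo
    return out


def simple_state(spikes: SpikeRecord, t: float, cfg: StateConfig) -> SimpleState:
    """Binary vector: 1 iff the neuron spiked within (t - tau, t]."""
    if t < cfg.simple_window:
        raise ValueError("t must be >= tau")
    ids = cfg.ids()
    counts = _counts_in_windows(spikes, ids, np.array([t]), cfg.simple_window)
    return tuple(int(c > 0) for c in counts[:, 0])


def markov_state(spikes: SpikeRecord, t: float, cfg: StateConfig) -> MarkovState:
    """Recent spike history within (t - T, t], offsets relative to t - T."""
    T = cfg.markov_window
    if t < T:
        raise ValueError("t must be >= T")
    ids = cfg.ids()
    offs = []
    for nid in ids:
        ts = spikes.spikes_of(nid)
        sel = ts[(ts > t - T) & (ts <= t)]
        offs.append(tuple(float(x - (t - T)) for x in sel))
    return MarkovState(offsets=tuple(offs), window=T)


def _grid(t_start: float, t_end: float, dt_sample: float) -> np.ndarray:
    n = int(np.floor((t_end - t_start) / dt_sample + 1e-9)) + 1
    g = t_start + dt_sample * np.arange(n)
    return g[g <= t_end + 1e-9]


def _state_matrix(spikes: SpikeRecord, cfg: StateConfig,
                  t_grid: np.ndarray) -> np.ndarray:
    ids = cfg.ids()
    counts = _counts_in_windows(spikes, ids, t_grid, cfg.simple_window)
    return (counts > 0).astype(np.int8).T       # (n_grid, n_ids)


def _freq_from_states(mat: np.ndarray, **kw) -> EmpiricalDistribution:
    if mat.shape[0] == 0:
        raise ValueError("empty sampling grid")
    uniq, counts = np.unique(mat, axis=0, return_counts=True)
    n = mat.shape[0]
    freq = {tuple(int(b) for b in row): c / n for row, c in zip(uniq, counts)}
    # exact renormalization guard against accumulated fp error
    tot = sum(freq.values())
    if tot != 1.0:
        freq = {k: v / tot for k, v in freq.items()}
    return EmpiricalDistribution(freq, n_samples=n, **kw)


def empirical_distribution(spikes: SpikeRecord, cfg: StateConfig,
                           t_start: float, t_end: float) -> EmpiricalDistribution:
    """Relative time spent in each simple state, sampled on the grid
    ``t_start, t_start + dt_sample, ..., <= t_end``."""
    if t_end - t_start < cfg.dt_sample:
        raise ValueError("window shorter than one sampling step")
    grid = _grid(t_start, t_end, cfg.dt_sample)
    return _freq_from_states(_state_matrix(spikes, cfg, grid))


def estimate_marginal(spikes: SpikeRecord, neuron_set: Sequence[int],
                      target_state: Sequence[int], cfg: StateConfig,
                      window: Tuple[float, float]) -> float:
    """Probability of ``target_state`` on ``neuron_set`` under the
    empirical distribution estimated over ``window``."""
    sub_cfg = StateConfig(simple_window=cfg.simple_window,
                          markov_window=cfg.markov_window,
                          dt_sample=cfg.dt_sample,
                          subset=tuple(neuron_set))
    dist = empirical_distribution(spikes, sub_cfg, window[0], window[1])
    return dist.prob(tuple(target_state))


def map_readout(dist: EmpiricalDistribution) -> tuple:
    """Maximum-a-posteriori state; ties broken lexicographically (smaller
    bit-vector wins)."""
    if not dist.freq:
        raise ValueError("empty distribution")
    m = max(dist.freq.values())
    cands = [s for s, f in dist.freq.items() if f == m]
    return min(cands)


def phase_distribution(spikes: SpikeRecord, cfg: StateConfig,
                       period: float, phase: float, n_cycles: int,
                       t_burn: float = 0.0) -> EmpiricalDistribution:
    """Distribution of simple states sampled only at a fixed phase of a
    periodic drive: t = t_burn + phase + k * period, k = 0..n_cycles-1."""
    if not (0 <= phase < period):
        raise ValueError("require 0 <= phase < period")
    if n_cycles < 1:
        raise ValueError("need at least one cycle")
    grid = t_burn + phase + period * np.arange(n_cycles)
    grid = grid[grid >= cfg.simple_window]
    if grid.size == 0:
        raise ValueError("no valid phase samples (record too short)")
    return _freq_from_states(_state_matrix(spikes, cfg, grid),
                             phase=phase, period=period)


def trajectory_distribution(spikes: SpikeRecord, cfg: StateConfig,
                            length: float, t_start: float,
                            t_end: float) -> EmpiricalDistribution:
    """Distribution over tuples of consecutive simple states spanning
    ``length`` ms (must be a positive multiple of dt_sample).

    At ``length == dt_sample`` this reduces exactly to
    :func:`empirical_distribution` (singleton trajectories).
    """
    k = int(round(length / cfg.dt_sample))
    if k < 1 or abs(k * cfg.dt_sample - length) > 1e-9:
        raise ValueError("length must be a positive multiple of dt_sample")
    grid = _grid(t_start, t_end, cfg.dt_sample)
    if grid.size < k:
        raise ValueError("record too short for requested trajectory length")
    mat = _state_matrix(spikes, cfg, grid)
    n_traj = mat.shape[0] - k + 1
    rows = []
    for i in range(n_traj):
        rows.append(tuple(tuple(int(b) for b in mat[i + j]) for j in range(k)))
    freq: Dict[tuple, float] = {}
    for r in rows:
        freq[r] = freq.get(r, 0.0) + 1.0 / n_traj
    tot = sum(freq.values())
    freq = {s: f / tot for s, f in freq.items()}
    if k == 1:
        freq = {s[0]: f for s, f in freq.items()}
    return EmpiricalDistribution(freq, n_samples=n_traj)


def detect_attractor_transitions(spikes: SpikeRecord, pool_A: Sequence[int],
                                 pool_B: Sequence[int], cfg: StateConfig,
                                 period: Optional[float] = None,
                                 t_start: Optional[float] = None,
                                 t_end: Optional[float] = None):
    """Detect handovers between two attractor pools.

    A pool is *active* at a grid time iff more than two of its neurons
    have an active simple-state bit.  A transition is a maximal segment
    separating a (A active, B inactive) period from a (B active, A
    inactive) period, or vice versa; its time is the midpoint of the
    intermediate segment and its phase is that time modulo ``period``.

    Returns a list of ``(time_ms, phase_ms)``; phase is None when no
    period is given.
    """
    if set(pool_A) & set(pool_B):
        raise ValueError("pools must be disjoint")
    if t_start is None:
        t_start = cfg.simple_window
    if t_end is None:
        t_end = float(spikes.times[-1]) if len(spikes) else t_start
    grid = _grid(t_start, t_end, cfg.dt_sample)
    ca = _counts_in_windows(spikes, list(pool_A), grid, cfg.simple_window) > 0
    cb = _counts_in_windows(spikes, list(pool_B), grid, cfg.simple_window) > 0
    a_act = ca.sum(axis=0) > 2
    b_act = cb.sum(axis=0) > 2
    # classify each grid point: +1 = A only, -1 = B only, 0 = ambiguous
    label = np.where(a_act & ~b_act, 1, np.where(b_act & ~a_act, -1, 0))
    out = []
    last_def = None          # (index, label) of last definite point
    for i, lab in enumerate(label):
        if lab == 0:
            continue
        if last_def is not None and lab != label[last_def]:
            # handover: intermediate segment is (last_def, i)
            mid = 0.5 * (grid[last_def] + grid[i])
            out.append((float(mid), float(mid % period) if period else None))
        last_def = i
    return out
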