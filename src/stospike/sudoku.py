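"""Constraint satisfaction by winner-take-all spiking networks; Sudoku.

A CSP with one-hot variables is compiled into a spiking network: each
(variable, value) pair is represented by a local group of ``N_E``
pyramidal cells, and every uniqueness constraint (at most one value
active in a set of (variable, value) members) becomes a winner-take-all
(WTA) motif: a single inhibitory neuron reciprocally connected to all
member cells.  For Sudoku there are 81 field motifs (one digit per
field) and 9 * 27 = 243 group motifs (each digit at most once per row,
column and 3x3 subgrid), 324 WTA motifs in total; every pyramidal cell
participates in exactly 4 of them.

Neurons are escape-noise units with rectangular-pulse synapses, so the
network is a proper stochastic sampler with a unique stationary
distribution; peaks of that distribution sit at assignments satisfying
many constraints, and the network performs a parallel stochastic search
that visits the solution from any initial condition.  Givens are
imposed as constant potential offsets: strongly positive on the cells
of the given digit, negative on cells of conflicting digits.

The value of a variable at time t is read out from recent activity:
value v is *active* iff any cell of its group fired within (t - tau, t].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .network import (NetworkModel, NeuronParams, SpikeRecord, SynapseParams)

__all__ = [
    "SudokuPuzzle", "CSPNetwork", "WTA_DEFAULTS", "encode_sudoku",
    "encode_generic_csp", "decode", "performance", "performance_curve",
    "solve_time", "sudoku_experiment", "parse_puzzle", "BUNDLED_HARD_PUZZLE",
]


# --------------------------------------------------------------------------
# puzzles

# Synthetic hard 26-given puzzle with a verified unique solution,
# bundled as the package's reference instance.  Generated with a
# uniqueness-checking backtracking solver; it is not solvable by
# naked/hidden singles alone.  Row-major, 0 = blank.
BUNDLED_HARD_PUZZLE = (
    "030250040408000000000049005003006000000700100000590000000120809"
    "020004630010003500",
    "639251748458367912172849365583416297294738156761592483346125879"
    "825974631917683524",
)


def parse_puzzle(s: str) -> np.ndarray:
    """Parse an 81-character row-major puzzle string ('.' or '0' = blank)."""
    s = s.strip().replace(".", "0")
    if len(s) != 81 or not s.isdigit():
        raise ValueError("puzzle must be 81 characters of digits 0-9 or '.'")
    return np.array([int(c) for c in s], dtype=np.int64).reshape(9, 9)


def _units() -> List[List[int]]:
    """The 27 Sudoku units (9 rows, 9 columns, 9 subgrids) as cell lists."""
    units = []
    for r in range(9):
        units.append([r * 9 + c for c in range(9)])
    for c in range(9):
        units.append([r * 9 + c for r in range(9)])
    for br in range(3):
        for bc in range(3):
            units.append([(3 * br + r) * 9 + 3 * bc + c
                          for r in range(3) for c in range(3)])
    return units


@dataclass
class SudokuPuzzle:
    """A 9x9 puzzle; 0 marks blanks.  ``solution`` optional but required
    by the performance/solve-time metrics."""

    cells: np.ndarray
    solution: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if isinstance(self.cells, str):
            self.cells = parse_puzzle(self.cells)
        if isinstance(self.solution, str):
            self.solution = parse_puzzle(self.solution)
        self.cells = np.asarray(self.cells, np.int64).reshape(9, 9)
        flat = self.cells.ravel()
        for unit in _units():
            vals = [flat[i] for i in unit if flat[i] != 0]
            if len(vals) != len(set(vals)):
                raise ValueError("inconsistent givens (duplicate in a unit)")
        if self.solution is not None:
            sol = np.asarray(self.solution, np.int64).reshape(9, 9)
            if np.any((sol < 1) | (sol > 9)):
                raise ValueError("solution must be digits 1-9")
            s = sol.ravel()
            for unit in _units():
                if len({s[i] for i in unit}) != 9:
                    raise ValueError("solution violates a uniqueness rule")
            mask = flat != 0
            if np.any(s[mask] != flat[mask]):
                raise ValueError("solution does not extend the givens")
            self.solution = sol

    @property
    def n_givens(self) -> int:
        return int(np.sum(self.cells != 0))

    @classmethod
    def bundled_hard(cls) -> "SudokuPuzzle":
        p, s = BUNDLED_HARD_PUZZLE
        return cls(parse_puzzle(p), parse_puzzle(s))


# --------------------------------------------------------------------------
# WTA compilation

# One config block for every redacted network constant, with the values
# the tuning procedure settled on (see docs/methods.md for the
# procedure and the regime analysis).  Amplitudes are rectangular
# potential pulses in mV.
WTA_DEFAULTS: Dict[str, float] = {
    "n_per_group": 4,          # N_E pyramidal cells per (variable, value)
    "exc_threshold_gap": -2.0,   # V_T(exc) - E_L, mV; negative = low threshold
    "inh_threshold_gap": 2.0,    # V_T(inh) - E_L, mV
    "exc_r0": 0.01,            # 1/ms
    "inh_r0": 0.01,
    "exc_rate_cap": 0.85,      # 1/ms; also sets the spontaneous churn rate
    "inh_rate_cap": 5.0,
    "hazard_slope": 2.0,       # dV, mV
    "exc_refractory": 5.0,     # ms
    "inh_refractory": 5.0,     # ms
    "w_EI": 14.0,              # mV, pyramidal -> motif inhibitory neuron
    "w_IE": 10.0,              # mV, motif inhibitory neuron -> pyramidal
    "w_IE_group": None,        # optional distinct strength for the
                               # row/column/subgrid (uniqueness-group)
                               # motifs; None = same as w_IE
    "w_EE": 16.0,              # mV, recurrent excitation within a digit group
    "pulse_EI": 10.0,          # ms
    "pulse_IE": 6.0,           # ms
    "pulse_EE": 10.0,          # ms
    "delay": 0.5,              # ms, all synapses
    "clamp_on": 15.0,          # mV, cells of a given digit
    "clamp_off": -30.0,        # mV, cells of conflicting digits in given fields
    "dt": 0.5,                 # ms, simulation step
    "tau_readout": 10.0,       # ms, activity window of the decoder
    # optional short-term depression on the within-group excitation
    # (off by default; see docs/methods.md)
    "stp_EE_U": None,
    "stp_EE_D": 400.0,
    "stp_EE_F": 1.0,
}


@dataclass
class CSPNetwork:
    """A CSP compiled to a spiking network.

    ``var_map[(variable, value)]`` lists the pyramidal-cell ids of that
    group; ``motifs`` lists WTA motifs as (member cell ids, inhibitory
    neuron id); ``clamp`` maps neuron id -> constant potential offset.
    """

    net: NetworkModel
    variables: List
    domains: Dict
    var_map: Dict[Tuple, List[int]]
    motifs: List[Tuple[List[int], int]]
    clamp: Dict[int, float]
    params: Dict[str, float]
    n_field_motifs: int = 0

    @property
    def n_pyramidal(self) -> int:
        return sum(len(v) for v in self.var_map.values())

    def group_of_cell(self) -> Dict[int, Tuple]:
        out = {}
        for key, ids in self.var_map.items():
            for i in ids:
                out[i] = key
        return out

    def motif_membership_counts(self) -> Dict[int, int]:
        counts: Dict[int, int] = {}
        for members, _ in self.motifs:
            for i in members:
                counts[i] = counts.get(i, 0) + 1
        return counts


def encode_generic_csp(variables: Sequence, domains: Dict,
                       uniqueness_groups: Sequence[Sequence[Tuple]],
                       clamp_values: Optional[Dict] = None,
                       params: Optional[Dict[str, float]] = None) -> CSPNetwork:
    """Compile a one-hot CSP into a WTA spiking network.

    ``domains[v]`` is the value list of variable ``v``; each variable
    contributes one one-hot (domain) WTA motif over all its groups.
    ``uniqueness_groups`` are additional member sets of (variable,
    value) pairs, each compiled to one WTA motif.  ``clamp_values``
    optionally fixes variables: ``{variable: value}`` clamps the chosen
    value's cells up and all siblings down.
    """
    p = dict(WTA_DEFAULTS)
    if params:
        p.update(params)
    n_e = int(p["n_per_group"])
    if n_e < 1:
        raise ValueError("need at least one cell per group")
    for grp in uniqueness_groups:
        if not grp:
            raise ValueError("empty uniqueness group")

    neurons: List[NeuronParams] = []
    var_map: Dict[Tuple, List[int]] = {}
    EL = -70.0
    exc = dict(
        hazard_base_rate=p["exc_r0"], hazard_threshold=EL + p["exc_threshold_gap"],
        hazard_slope=p["hazard_slope"], rate_cap=p["exc_rate_cap"],
        refractory_abs=p["exc_refractory"], resting_potential=EL,
        is_inhibitory=False,
    )
    inh = dict(
        hazard_base_rate=p["inh_r0"], hazard_threshold=EL + p["inh_threshold_gap"],
        hazard_slope=p["hazard_slope"], rate_cap=p["inh_rate_cap"],
        refractory_abs=p["inh_refractory"], resting_potential=EL,
        is_inhibitory=True,
    )
    clamp: Dict[int, float] = {}
    clamp_values = clamp_values or {}
    for v in variables:
        for val in domains[v]:
            ids = []
            for _ in range(n_e):
                offset = 0.0
                if v in clamp_values:
                    offset = (p["clamp_on"] if clamp_values[v] == val
                              else p["clamp_off"])
                neurons.append(NeuronParams(bias_potential=offset, **exc))
                nid = len(neurons) - 1
                ids.append(nid)
                if offset:
                    clamp[nid] = offset
            var_map[(v, val)] = ids

    synapses: List[SynapseParams] = []
    # recurrent excitation within each value group: a group that starts
    # firing sustains itself as a small assembly (the persistence that
    # lets tentative assignments constrain the rest of the network).
    # Optional short-term depression on these synapses makes incumbent
    # assemblies fatigue, so exploration is biased away from stale
    # choices without extra noise.
    stp_ee = None
    if p.get("stp_EE_U"):
        from .network import STPParams
        stp_ee = STPParams(U=p["stp_EE_U"], D=p["stp_EE_D"],
                           F=p.get("stp_EE_F", 1.0))
    if p["w_EE"] > 0:
        for ids in var_map.values():
            for a in ids:
                for b in ids:
                    if a != b:
                        synapses.append(SynapseParams(
                            pre=a, post=b, weight=p["w_EE"], delay=p["delay"],
                            kind="current-rect", pulse_length=p["pulse_EE"],
                            stp=stp_ee))
    motifs: List[Tuple[List[int], int]] = []

    def add_motif(members: List[int], w_ie: float) -> None:
        neurons.append(NeuronParams(**inh))
        inh_id = len(neurons) - 1
        for m in members:
            synapses.append(SynapseParams(
                pre=m, post=inh_id, weight=p["w_EI"], delay=p["delay"],
                kind="current-rect", pulse_length=p["pulse_EI"]))
            synapses.append(SynapseParams(
                pre=inh_id, post=m, weight=w_ie, delay=p["delay"],
                kind="current-rect", pulse_length=p["pulse_IE"]))
        motifs.append((members, inh_id))

    w_ie_group = p.get("w_IE_group") or p["w_IE"]
    # one-hot (domain) motifs
    n_domain = 0
    for v in variables:
        members = [i for val in domains[v] for i in var_map[(v, val)]]
        add_motif(members, p["w_IE"])
        n_domain += 1
    # uniqueness-group motifs
    for grp in uniqueness_groups:
        members = []
        for (v, val) in grp:
            members.extend(var_map[(v, val)])
        add_motif(members, w_ie_group)

    net = NetworkModel(neurons=neurons, synapses=synapses,
                       metadata={"kind": "csp-wta"})
    return CSPNetwork(net=net, variables=list(variables), domains=dict(domains),
                      var_map=var_map, motifs=motifs, clamp=clamp, params=p,
                      n_field_motifs=n_domain)


def encode_sudoku(puzzle: SudokuPuzzle, n_per_group: int = 4,
                  params: Optional[Dict[str, float]] = None) -> CSPNetwork:
    """Compile a Sudoku puzzle into its WTA network.

    81 variables (fields) with domain 1..9; 81 field (one-hot) motifs
    and 243 group motifs (one per digit per row/column/subgrid).  Givens
    are clamped by constant potential offsets.
    """
    p = dict(params or {})
    p["n_per_group"] = n_per_group
    variables = list(range(81))
    domains = {f: list(range(1, 10)) for f in variables}
    groups = []
    for unit in _units():
        for d in range(1, 10):
            groups.append([(f, d) for f in unit])
    flat = puzzle.cells.ravel()
    clamp_values = {f: int(flat[f]) for f in variables if flat[f] != 0}
    cspnet = encode_generic_csp(variables, domains, groups,
                                clamp_values=clamp_values, params=p)
    cspnet.net.metadata["puzzle"] = puzzle
    return cspnet


# --------------------------------------------------------------------------
# readout

def decode(cspnet: CSPNetwork, spikes: SpikeRecord, t: float,
           tau: Optional[float] = None) -> Dict:
    """Active value set per variable at time t (spike within (t-tau, t])."""
    tau = tau if tau is not None else cspnet.params["tau_readout"]
    if t < tau:
        raise ValueError("t must be >= tau")
    out: Dict = {v: set() for v in cspnet.variables}
    win = spikes.in_window(t - tau, t)
    group = cspnet.group_of_cell()
    for nid in win.neuron_ids:
        key = group.get(int(nid))
        if key is not None:
            out[key[0]].add(key[1])
    return out


def _group_spike_times(cspnet: CSPNetwork, spikes: SpikeRecord):
    """Spike times per (variable index, value) group, sorted."""
    group = cspnet.group_of_cell()
    times: Dict[Tuple, list] = {k: [] for k in cspnet.var_map}
    for nid, t in zip(spikes.neuron_ids, spikes.times):
        key = group.get(int(nid))
        if key is not None:
            times[key].append(t)
    return {k: np.asarray(v) for k, v in times.items()}


def performance_curve(cspnet: CSPNetwork, spikes: SpikeRecord,
                      grid: np.ndarray, tau: Optional[float] = None,
                      mode: str = "singleton") -> np.ndarray:
    """Fraction of variables decoded to their correct value, per grid time.

    ``singleton`` (default): a variable counts as correct iff its active
    set is exactly {solution value}.  ``lenient``: iff the solution value
    is active, regardless of other active values.
    """
    puzzle: SudokuPuzzle = cspnet.net.metadata.get("puzzle")
    if puzzle is None or puzzle.solution is None:
        raise ValueError("performance requires a puzzle with known solution")
    tau = tau if tau is not None else cspnet.params["tau_readout"]
    grid = np.asarray(grid, float)
    sol = puzzle.solution.ravel()
    gtimes = _group_spike_times(cspnet, spikes)
    nvar = len(cspnet.variables)
    correct_active = np.zeros((nvar, grid.size), bool)
    other_active = np.zeros((nvar, grid.size), bool)
    for (v, val), ts in gtimes.items():
        if ts.size == 0:
            continue
        hi = np.searchsorted(ts, grid, side="right")
        lo = np.searchsorted(ts, grid - tau, side="right")
        act = hi > lo
        if val == sol[v]:
            correct_active[v] |= act
        else:
            other_active[v] |= act
    if mode == "singleton":
        ok = correct_active & ~other_active
    elif mode == "lenient":
        ok = correct_active
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ok.mean(axis=0)


def performance(cspnet: CSPNetwork, spikes: SpikeRecord, t: float,
                tau: Optional[float] = None,
                mode: str = "singleton") -> float:
    """Fraction of variables decoded to their correct value at time t."""
    return float(performance_curve(cspnet, spikes, np.array([t]), tau, mode)[0])


def solve_time(cspnet: CSPNetwork, spikes: SpikeRecord,
               grid: np.ndarray, tau: Optional[float] = None,
               mode: str = "singleton") -> Optional[float]:
    """Earliest grid time at which performance reaches 1.0, or None."""
    perf = performance_curve(cspnet, spikes, grid, tau, mode)
    idx = np.nonzero(perf >= 1.0)[0]
    return float(np.asarray(grid)[idx[0]]) if idx.size else None


# --------------------------------------------------------------------------
# experiment harness

def sudoku_experiment(puzzle: SudokuPuzzle, runs: int, max_duration: float,
                      seed: Optional[int] = None, n_per_group: int = 4,
                      params: Optional[Dict[str, float]] = None,
                      dt_sample: float = 5.0, burn_in: float = 0.0,
                      stop_when_solved: bool = False,
                      perf_curve_until: Optional[float] = None,
                      chunk: float = 2000.0,
                      mode: str = "singleton") -> Dict:
    """Repeated independent stochastic runs of the Sudoku network.

    Returns a dict with ``solve_times`` (ms; unsolved runs reported in
    ``n_unsolved``), ``perf_grid`` / ``mean_performance`` (average
    performance curve over runs, up to ``perf_curve_until`` or
    ``max_duration``), and ``occupancy`` (pooled fraction of post
    ``burn_in`` grid times at which performance equals 1.0).

    Each run is seeded independently from ``seed``; simulation proceeds
    in chunks so runs can stop early once solved.
    """
    if runs < 1:
        raise ValueError("need at least one run")
    from .simulate import run as _run

    cspnet = encode_sudoku(puzzle, n_per_group=n_per_group, params=params)
    p = cspnet.params
    dt = p["dt"]
    tau = p["tau_readout"]
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=runs)

    curve_until = perf_curve_until or max_duration
    perf_grid = np.arange(tau, curve_until + 1e-9, dt_sample)
    mean_perf = np.zeros(perf_grid.size)
    perf_counts = np.zeros(perf_grid.size)

    solve_times: List[float] = []
    n_unsolved = 0
    occ_hits = 0
    occ_total = 0

    for r in range(runs):
        state = None
        solved_at: Optional[float] = None
        t_done = 0.0
        prev_tail = SpikeRecord()
        records: List[SpikeRecord] = []
        while t_done < max_duration - 1e-9:
            this = min(chunk, max_duration - t_done)
            if state is None:
                res = _run(cspnet.net, this, dt=dt, seed=int(run_seeds[r]))
            else:
                res = _run(cspnet.net, this, dt=dt, initial_state=state)
            state = res.state
            rec = res.spikes.shifted(t_done)
            records.append(rec)
            # grid points covered by this chunk (windows may reach back)
            g0 = max(tau, np.ceil((t_done) / dt_sample) * dt_sample)
            if t_done == 0.0:
                g0 = tau
            grid = np.arange(g0, t_done + this + 1e-9, dt_sample)
            grid = grid[grid > t_done - 1e-9] if t_done else grid
            if grid.size:
                both = SpikeRecord.concatenate([prev_tail, rec])
                perf = performance_curve(cspnet, both, grid, tau, mode)
                if solved_at is None:
                    hit = np.nonzero(perf >= 1.0)[0]
                    if hit.size:
                        solved_at = float(grid[hit[0]])
                sel = grid > burn_in
                occ_hits += int(np.sum(perf[sel] >= 1.0))
                occ_total += int(np.sum(sel))
                msel = (grid >= perf_grid[0] - 1e-9) & \
                       (grid <= perf_grid[-1] + 1e-9)
                if np.any(msel):
                    gi = np.round((grid[msel] - perf_grid[0]) / dt_sample
                                  ).astype(int)
                    mean_perf[gi] += perf[msel]
                    perf_counts[gi] += 1
            t_done += this
            prev_tail = rec.in_window(t_done - tau, t_done)
            if stop_when_solved and solved_at is not None:
                break
        if solved_at is not None:
            solve_times.append(solved_at)
        else:
            n_unsolved += 1

    with np.errstate(invalid="ignore"):
        mean_curve = np.where(perf_counts > 0, mean_perf / perf_counts, np.nan)
    return {
        "solve_times": solve_times,
        "n_unsolved": n_unsolved,
        "perf_grid": perf_grid,
        "mean_performance": mean_curve,
        "occupancy": occ_hits / occ_total if occ_total else float("nan"),
        "n_runs": runs,
    }
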