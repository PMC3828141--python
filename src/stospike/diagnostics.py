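"""Gelman-Rubin convergence diagnostics on network-state samples.

The potential scale reduction factor (PSRF) compares the spread of M
independent chains started from different initial states.  With N
samples per chain taken from the second half of the record, (t/2, t],

    W = mean over chains of the per-chain sample variance
    B = N * variance over chains of the chain means
    R_hat = ((N - 1)/N * W + B/N) / W        (variance form)

R_hat near 1 indicates that the between-chain spread is explained by
within-chain variability, i.e. convergence to a common distribution.
If W = 0 (a variable constant across all runs, e.g. a neuron that never
fires) R_hat is defined as 1.

Note on thresholds: the literature uses both this variance form and its
square root.  A threshold of ~1.2 applies to the variance form; the
often-quoted 1.1 applies to the square-root form (1.1**2 ~ 1.2).

The multivariate version (MPSRF) for d-dimensional samples is

    R_hat_p = (N - 1)/N + (M + 1)/M * lambda_max(W^{-1} B / N)

with W and B the within/between covariance matrix estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np

from .network import NetworkModel, InputProcess
from .states import StateConfig, _counts_in_windows

__all__ = [
    "ChainSet", "PSRFCurve", "psrf", "mpsrf", "convergence_time",
    "run_convergence_experiment",
    "PSRF_THRESHOLD_VARIANCE_FORM", "PSRF_THRESHOLD_SQRT_FORM",
]

PSRF_THRESHOLD_VARIANCE_FORM = 1.2
PSRF_THRESHOLD_SQRT_FORM = 1.1


@dataclass
class ChainSet:
    """Samples from M independent runs on a common time grid.

    ``samples`` has shape (M, n_times) for scalar variables or
    (M, n_times, d) for vector variables; ``grid`` is in ms.
    """

    grid: np.ndarray
    samples: np.ndarray
    variable: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        self.samples = np.asarray(self.samples, float)
        if self.samples.shape[0] < 2:
            raise ValueError("need at least 2 chains")
        if self.samples.shape[1] != self.grid.size:
            raise ValueError("samples and grid disagree on n_times")

    @property
    def M(self) -> int:
        return self.samples.shape[0]

    @property
    def is_vector(self) -> bool:
        return self.samples.ndim == 3


@dataclass
class PSRFCurve:
    """R_hat as a function of analysis time t (window (t/2, t])."""

    times: np.ndarray
    r_hat: np.ndarray
    variable: str = ""
    form: str = "variance"


def _window_slice(grid: np.ndarray, t: float) -> np.ndarray:
    """Indices of grid points in the analysis window (t/2, t]."""
    return np.nonzero((grid > t / 2) & (grid <= t + 1e-9))[0]


def psrf(chains: ChainSet, t: float) -> float:
    """Univariate potential scale reduction factor at analysis time t."""
    if chains.is_vector:
        raise ValueError("psrf expects scalar-variable chains; use mpsrf")
    idx = _window_slice(chains.grid, t)
    if idx.size < 2:
        raise ValueError("analysis window (t/2, t] holds fewer than 2 samples")
    x = chains.samples[:, idx]                     # (M, N)
    N = x.shape[1]
    W = float(np.mean(np.var(x, axis=1, ddof=1)))
    B = N * float(np.var(np.mean(x, axis=1), ddof=1))
    if W == 0.0:
        return 1.0
    return ((N - 1) / N * W + B / N) / W


def mpsrf(chains: ChainSet, t: float, ridge: float = 1e-10) -> float:
    """Multivariate PSRF (largest-eigenvalue form) at analysis time t.

    Coordinates that are constant across all chains in the window are
    dropped (the multivariate analogue of the W = 0 rule); if all are
    constant the result is 1.  A small ridge proportional to trace(W)/d
    regularizes a singular within-covariance.
    """
    if not chains.is_vector:
        raise ValueError("mpsrf expects vector-variable chains")
    idx = _window_slice(chains.grid, t)
    if idx.size < 2:
        raise ValueError("analysis window (t/2, t] holds fewer than 2 samples")
    x = chains.samples[:, idx, :]                  # (M, N, d)
    M, N, d = x.shape
    if d == 0:
        raise ValueError("zero-dimensional variable")
    keep = ~np.all(x == x[0:1, 0:1, :], axis=(0, 1))
    if not np.any(keep):
        return 1.0
    x = x[:, :, keep]
    d = x.shape[2]
    chain_means = x.mean(axis=1)                   # (M, d)
    W = np.zeros((d, d))
    for m in range(M):
        c = x[m] - chain_means[m]
        W += c.T @ c / (N - 1)
    W /= M
    gm = chain_means.mean(axis=0)
    cb = chain_means - gm
    B = N * (cb.T @ cb) / (M - 1)                  # B (covariance * N)
    tr = np.trace(W)
    if tr <= 0:
        return 1.0
    Wr = W + ridge * tr / d * np.eye(d)
    lam = float(np.max(np.linalg.eigvals(np.linalg.solve(Wr, B / N)).real))
    return (N - 1) / N + (M + 1) / M * lam


def convergence_time(curve: PSRFCurve, threshold: float) -> Optional[float]:
    """First grid time after which R_hat stays <= threshold forever;
    None if the curve never settles below the threshold."""
    r = np.asarray(curve.r_hat, float)
    if r.size == 0:
        raise ValueError("empty curve")
    ok = r <= threshold
    # last index where the curve is above threshold
    above = np.nonzero(~ok)[0]
    if above.size == 0:
        return float(curve.times[0])
    if above[-1] == r.size - 1:
        return None
    return float(curve.times[above[-1] + 1])


def psrf_curve(chains: ChainSet, times: Sequence[float],
               variable: str = "") -> PSRFCurve:
    vals = []
    fn = mpsrf if chains.is_vector else psrf
    for t in times:
        vals.append(fn(chains, t))
    return PSRFCurve(np.asarray(times, float), np.asarray(vals), variable)


# --------------------------------------------------------------------------
# full experiment: M runs from random initial states

def run_convergence_experiment(
        net: NetworkModel, M: int, duration: float,
        mode: str = "marginal", seed: Optional[int] = None,
        dt: float = 0.1, tau: float = 20.0, dt_sample: float = 5.0,
        subset: Optional[Sequence[int]] = None,
        pairs: Optional[Sequence[tuple]] = None,
        prep_duration: float = 250.0,
        prep_rate_range: tuple = (0.0, 0.05),
        analysis_times: Optional[Sequence[float]] = None,
        chain_seeds: Optional[Sequence[tuple]] = None):
    """Run M chains from random initial states and compute PSRF curves.

    Each chain receives its own preparatory phase in which every input
    neuron is assigned a random constant rate drawn uniformly from
    ``prep_rate_range`` (1/ms); when the network has no dedicated input
    neurons, random per-neuron bias potentials stand in.  After the
    preparatory phase the rng is re-seeded per chain and the main phase
    of ``duration`` ms is simulated.

    Modes: ``marginal`` (one scalar chain per neuron bit), ``pairwise``
    (product of two neurons' bits per listed pair), ``multivariate``
    (one vector chain over ``subset``, MPSRF), ``readout`` (marginal
    analysis restricted to the network's observer neuron, which must be
    recorded in ``net.metadata["readout_id"]``).

    Returns ``(curves, mean_curve, worst_curve)``; for multivariate mode
    the three coincide.
    """
    if M < 2:
        raise ValueError("need at least 2 chains")
    if mode == "readout":
        ro = net.metadata.get("readout_id")
        if ro is None:
            raise ValueError("readout mode needs metadata['readout_id'] "
                             "(see circuits.attach_readout)")
        subset = [ro]
        mode = "marginal"
    from .simulate import prepare_initial_state, run as _run

    if chain_seeds is None:
        rng = np.random.default_rng(seed)
        chain_seeds = rng.integers(0, 2**31 - 1, size=(M, 2))
    else:
        chain_seeds = np.asarray(chain_seeds, np.int64).reshape(M, 2)
    # protocol guard: chains must start from different initial states
    if len({int(s) for s in chain_seeds[:, 0]}) < M:
        raise ValueError(
            "duplicate preparatory seeds: chains would share initial states")

    grid = np.arange(tau, duration + 1e-9, dt_sample)
    ids = list(subset) if subset is not None else list(range(net.n_neurons))
    ids = [i for i in ids if i not in set(net.input_neuron_ids)]

    bits_per_chain = []
    input_ids = list(net.input_neuron_ids)
    for m in range(M):
        prep_seed, main_seed = int(chain_seeds[m, 0]), int(chain_seeds[m, 1])
        prep_rng = np.random.default_rng(prep_seed)
        if input_ids:
            rates = prep_rng.uniform(*prep_rate_range, size=len(input_ids))
            prep_inputs = [InputProcess(neuron_ids=tuple(input_ids),
                                        kind="constant",
                                        per_neuron_rates=tuple(rates))]
            prep_inputs += [ip for ip in net.inputs]
            state, _ = prepare_initial_state(
                net, prep_inputs, prep_duration, prep_seed, main_seed, dt=dt)
        else:
            # no input neurons: randomize initial conditions directly
            state, _ = prepare_initial_state(
                net, list(net.inputs), prep_duration, prep_seed, main_seed,
                dt=dt)
        res = _run(net, duration, dt=dt, initial_state=state)
        counts = _counts_in_windows(res.spikes, ids, grid, tau)
        bits_per_chain.append((counts > 0).astype(float))   # (n_ids, n_grid)
    bits = np.stack(bits_per_chain)                         # (M, n_ids, n_grid)

    if analysis_times is None:
        analysis_times = [t for t in grid if _window_slice(grid, t).size >= 2]

    curves: List[PSRFCurve] = []
    if mode == "marginal":
        for j, nid in enumerate(ids):
            cs = ChainSet(grid, bits[:, j, :], variable=f"neuron_{nid}")
            curves.append(psrf_curve(cs, analysis_times, cs.variable))
    elif mode == "pairwise":
        if not pairs:
            raise ValueError("pairwise mode needs a list of neuron pairs")
        pos = {nid: j for j, nid in enumerate(ids)}
        for a, b in pairs:
            prod = bits[:, pos[a], :] * bits[:, pos[b], :]
            cs = ChainSet(grid, prod, variable=f"pair_{a}x{b}")
            curves.append(psrf_curve(cs, analysis_times, cs.variable))
    elif mode == "multivariate":
        cs = ChainSet(grid, np.transpose(bits, (0, 2, 1)),
                      variable="subset")
        curves.append(psrf_curve(cs, analysis_times, cs.variable))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    allr = np.stack([c.r_hat for c in curves])
    at = np.asarray(analysis_times, float)
    mean_curve = PSRFCurve(at, allr.mean(axis=0), "mean")
    worst_curve = PSRFCurve(at, allr.max(axis=0), "worst")
    return curves, mean_curve, worst_curve
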