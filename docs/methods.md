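# Methods

## Model

All neurons are escape-noise (stochastic threshold) point neurons: at
membrane potential `V` the instantaneous firing rate is

    r(V) = min( r0 * exp((V - V_T) / dV), r_max )

with soft threshold `V_T`, threshold softness `dV`, rate at threshold
`r0` and a hard cap `r_max`. The cap is not cosmetic: it bounds the
probability of any spike in a finite window away from one, which is the
property that makes the network state a uniformly ergodic Markov chain
(see "Ergodicity oracle" below). After a spike the neuron is absolutely
refractory for `refractory_abs` ms and its membrane is then reset to the
resting potential. Defaults: `r0 = 0.01/ms`, `dV = 2 mV`,
`r_max = 1/ms`, `V_T = -55 mV`, all per neuron and configurable. These
are reconstructions in the style of the exponential escape-rate
literature, not measured values.

Two synapse models are implemented:

- **conductance-exp**: each presynaptic spike increments a conductance
  that decays exponentially (`tau_e = 5 ms`, `tau_i = 10 ms`); the
  membrane (C_m = 0.2 nF, g_L = 10 nS, E_L = -70 mV, E_exc = 0 mV,
  E_inh = -75 mV) integrates leak and synaptic currents by exponential
  Euler. Used by the cortical-microcircuit-style networks.
- **current-rect**: each spike contributes a rectangular
  *membrane-potential* pulse (amplitude in mV, fixed length). The
  potential seen by the hazard is then piecewise constant and the
  discrete-time simulation is exact up to quantizing pulse edges to the
  grid; this is the model used by the constraint-satisfaction networks,
  where it also admits a fast vectorized kernel.

Short-term plasticity follows the standard utilization/recovery
recurrences: amplitude of the k-th spike is `w * u_k * R_k` with
`u_1 = U`, `R_1 = 1`, `u_{k+1} = U + u_k (1-U) exp(-D_k/F)`,
`R_{k+1} = 1 + (R_k (1-u_k) - 1) exp(-D_k/D)`. Class means
(E->E: U=0.5, D=1100 ms, F=50 ms; E->I: 0.05/125/1200;
I->E: 0.25/700/20; I->I: 0.32/144/60) are used directly by the demo
circuits and as the means of truncated-Gaussian per-neuron draws (SD =
50% of the mean) in the laminar column.

### Simulation scheme

Time-stepped, default `dt = 0.1 ms` (0.5 ms for the rectangular-pulse
CSP networks, whose shortest synaptic delay is 0.5 ms and whose pulses
are >= 6 ms). In each step every non-refractory neuron fires with
probability `1 - exp(-r(V) dt)`; at most one spike per neuron per step
by construction. Spikes decided in step k are stamped at the end of the
step; a delay of m steps makes the spike effective from step k+m. The
minimum interspike interval equals `refractory_abs` exactly. One seeded
`numpy` generator per run; each step consumes exactly one uniform array
of length n, so runs are bit-reproducible and the accelerated
(numba-jitted) rectangular-pulse path, which consumes the same stream
in the same order, is bit-identical to the generic path (this is
asserted by a test). Halving dt changes the firing rate of a reference
two-neuron loop by under 5% (dominated by the `dt/2` bias of
discrete-time thinning).

Initial potentials are drawn uniformly between rest and the soft
threshold for networks with membrane dynamics; pure rectangular-pulse
networks have no free membrane state, so they start at rest.

The preparatory-phase protocol runs the network for `prep_duration`
under preparatory inputs with a dedicated seed, then re-seeds the
generator at t = 0: repeated calls with the same preparatory seed and
different main seeds reproduce the identical initial spike history with
divergent futures.

## Network states and distributions

A *simple state* at time t is the binary vector of which neurons spiked
in `(t - tau, t]` (default `tau = 20 ms`); a *Markov state* keeps the
full spike times in `(t - T, t]` (default `T = 100 ms`). All windows
are half-open on the left so a spike at the sampling instant counts
exactly once. Distributions are estimated as relative time spent in
each state on a regular sampling grid; "stationary" estimates discard
the first half of the record by default. Under periodic drive,
phase-specific distributions sample only at `t_burn + phi + k T_per`.
Trajectory distributions generalize to tuples of consecutive simple
states and reduce exactly to the plain distribution at one step.

Attractor transitions between two pools follow the
more-than-two-active-neurons rule: a pool is active when >2 of its
neurons have an active bit; a transition's time is the midpoint of the
ambiguous segment between one pool's exclusive activity and the
other's.

## Convergence diagnostics

The potential scale reduction factor is computed in its variance form
from the second half `(t/2, t]` of M chains: `W` the mean within-chain
variance, `B = N Var(chain means)`, `R = ((N-1)/N W + B/N)/W`, with
`R = 1` when `W = 0` (e.g. a never-firing neuron). The often-quoted
threshold 1.1 belongs to the square-root form; 1.2 is the matching
variance-form threshold, and both are exported as named constants. The
multivariate version uses the largest eigenvalue of `W^{-1} B / N`
(ridge `1e-10 tr(W)/d` against singular `W`; coordinates constant
across all chains are dropped, mirroring the univariate rule).
Convergence time is the first grid time after which the curve stays at
or below the threshold. The experiment driver runs M chains whose
initial states are randomized by per-input-neuron preparatory rates
drawn uniformly from 0-50 spikes/s (configurable), and refuses
duplicate preparatory seeds.

## Ergodicity oracle

For networks of <= 3 neurons whose synaptic memory fits in k history
bins the one-step kernel over all `2^(n k)` binary spike histories is
enumerated exactly (rectangular-pulse synapses make this exact;
conductance synapses are replayed over the bins as a quasi-stationary
approximation). On this surface the package *verifies* rather than
assumes:

- `alpha = min_s P^m(s -> resting)` is positive and at least
  `exp(-Lambda tau)` (no spike from any neuron for one memory window,
  `Lambda` = summed rate caps) — the Doeblin-type minorization;
- one memory window contracts the (un-halved) total variation between
  any two state distributions by at least `(1 - alpha)`;
- power iteration reaches the unique stationary distribution
  geometrically, and a long simulation of the same network matches it
  (TV <= 0.05);
- per-phase kernels of a periodically driven chain have a cyclically
  consistent family of phase-specific stationary distributions.

A deterministic kernel (`alpha = 0`) is reported as insufficiently
stochastic rather than silently accepted.

## Circuit families

The laminar column template ships as editable configuration
(`stospike/configs/laminar_default.yaml`) whose numeric tables are
clearly marked placeholders preserving laminar structure (within-layer
density, L4 -> L2/3 -> L5 feedforward, strong local inhibition, two
40-neuron Poisson input streams, per-pool background currents);
quantitative reproduction of a specific published column requires
transcribing its tables. Recurrent mean weights scale as `n_ref/n_new`
when resizing. The sparse network uses the stated probabilities
(E->E = E->I = 0.1, I->E = I->I = 0.9). Sequence networks use
forward/backward exponentially decaying chain weights
(`xi_f = 1.2`, `xi_b = 0.8` index units, `w0 = 50 nS`, chain soft
thresholds at -60 mV); these values were tuned until single waves
propagate in index order (rank correlation of first spikes > 0.8) —
single conductance EPSPs barely move an escape-noise neuron, so chains
need summation from several predecessors. The demo circuits fix
short-term-plasticity parameters at the class means; per-neuron random
draws occasionally produce near-zero utilization, which permanently
severs a chain link. The bistable network (two self-exciting pools,
mutual di-synaptic inhibition, `w_self = 1.8 nS`, bias 0.15 nA) spends
roughly a quarter of its time in each exclusive attractor state and
switches stochastically. The readout neuron receives exactly the
120/30/80/20/200/50 per-pool afferents with Gamma-distributed weights
and type-class short-term plasticity, and sends nothing back.

## Constraint satisfaction by WTA networks

Each (variable, value) pair is a group of `N_E = 4` pyramidal cells;
every variable contributes a one-hot motif and every uniqueness
constraint a group motif, each a single inhibitory neuron reciprocally
connected to all members ("population-like" inhibition). For Sudoku: 81
field motifs + 243 group motifs = 324, every cell in exactly 4. Givens
are imposed as constant potential offsets (+15 mV on the given digit's
cells — saturating their rate cap — and -30 mV on conflicting cells).
A value is read out as active if any of its cells spiked within
`tau_readout = 10 ms`; a variable is *correct* when its active set is
exactly the singleton solution value (a lenient mode that ignores extra
active values is available but not the default).

### Operating regime and how it was tuned

The shipped parameters are the end point of a systematic search, and
the reasoning is worth recording because the failure modes are
instructive:

1. Without within-group excitation no tentative assignment persists
   longer than one readout window, the network never communicates
   constraint information, and performance equals the givens fraction.
   Recurrent excitation inside each value group (`w_EE = 16 mV`, 10 ms
   pulses) turns groups into small assemblies that sustain themselves
   across inhibition cycles; this is also the natural reading of why
   multi-cell groups (`N_E > 1`) allow lower per-cell rates and weaker
   synapses.
2. The inhibitory neurons must re-arm quickly enough to cover the whole
   cycle: a 20 ms dead time with 10 ms pulses leaves half of every
   cycle uninhibited and destroys the winner-take-all; the default dead
   time is 5 ms with 6 ms inhibitory pulses.
3. The excitatory rate cap (0.85/ms) sets the spontaneous exploration
   rate: at an inhibition lapse the incumbent assembly re-fires with
   probability set by the cap, and the rare missed cycles are what
   allow contested fields to re-randomize.
4. Conflicts between mature assemblies in different fields are fought
   through a *shared* motif inhibitory neuron that suppresses both
   sides equally; with the default strengths these fights weaken both
   sides but are not reliably lethal, so the network can dwell long in
   locally consistent configurations that disagree with the unique
   global solution. Every regime we tested that makes conflicts lethal
   (uniform or group-specific `w_IE >= 18 mV`, inhibitory dead time
   <= 2 ms, short-term depression of the group excitation, global
   threshold oscillation) also prevents assemblies from forming out of
   the initial transient and collapses performance to the givens
   fraction.

The consequence, measured at the package's own defaults, is an honest
gap to the headline behaviour of the original demonstration: the mean
decoded performance on the bundled hard 26-given puzzle rises
monotonically to ~0.7-0.8 (maximum ~0.95) but reaches only ~0.6 within
the first 5 s, and complete solutions are heavy-tailed rare events
rather than ~29 s-mean arrivals. On an easy instance (60 givens) the
same network solves within seconds in nearly every run, and a 45-given
instance within tens of seconds (both checked by the shipped suite), so
the machinery — encoding, WTA dynamics, decoding — is sound and solve
time falls steeply with the number of givens. Development-time controls
(not part of the shipped suite) indicated that the limiting quantity is
the number of blank fields rather than the classical difficulty
rating: a naked-singles-solvable 26-given instance behaved like the
bundled one. The bundled stand-in (generated in-repo with a
uniqueness-checking solver, not solvable by naked/hidden singles) is
therefore representative of its given count for this solver class even
though the original puzzle exists only as a figure.

## Synthetic fixtures

The fixture generators produce spike records with statistics known by
construction: independent Poisson trains; a single neuron whose
activity bit is high for an exact target fraction of time (regular
active blocks, so the estimate's error is set by grid alignment, not
sampling); clean pool handovers with a known transition midpoint; and
periodically gated trains silent in the second half of every cycle.
They emulate the statistical structure the analyses assume — rates,
occupancies, periodicity, attractor alternation — and deliberately not
the fine temporal structure of real circuits (no refractoriness in the
Poisson trains, no rate adaptation); passing these tests validates the
estimators, not any biological claim.

## Problem sizes in the test suite

The default suite keeps simulations at desk scale: tiny rectangular
networks for oracle cross-checks (state spaces <= 256), 6-12 chains of
a 3-neuron toy for the Gelman-Rubin experiment, 300-600 neuron columns
for the laminar statistics, and 4-10 runs of the full 3240-neuron
Sudoku network for the solver checks, with run lengths of seconds. The
acceptance script runs the full protocol sizes (25/50/10 runs).
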