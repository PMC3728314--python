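# Methods

## Model

`sisqsd` implements Markovian susceptible–infectious–susceptible (SIS)
dynamics on a finite, static, weighted, possibly directed contact network.
The parameterisation is a rate matrix `T` — entry `T[i, j] >= 0` is the
Poisson rate at which individual `i` infects individual `j` while `i` is
infectious and `j` susceptible (row = infector, diagonal zero) — and a
strictly positive recovery-rate vector `g`.  The process is a
continuous-time Markov chain on the `2^N` subsets of infectious
individuals; the empty set is absorbing, and on a strongly connected
network the `2^N - 1` nonempty states form a single communicating class.

Three exact views of this one process are implemented and cross-checked:

1. **Master equation** (`exact`): the sub-generator `Q` restricted to the
   transient states.  Perron–Frobenius theory gives a simple dominant
   eigenvalue `-alpha` with positive eigenvectors on both sides.  The left
   eigenvector, normalised to total mass one, is the quasi-stationary
   distribution (QSD): the limiting law conditioned on non-extinction, the
   natural notion of endemic prevalence on a finite network where true
   endemic stationarity cannot exist.  The right eigenvector `w`, scaled
   to 1 at the all-infected state, gives the quasi-invasion probability:
   since `exp(Qt) -> exp(-alpha t) * w nu^T` for irreducible `Q`, the
   ratio of survival probabilities from initial state `A` and from
   all-infected converges to `w(A)`.  The spectral formula is how the
   limit is computed; tests validate it against the finite-`t` ratio
   evaluated with the matrix exponential.
2. **Event-driven simulation** (`gillespie`): the direct stochastic
   simulation algorithm with incremental per-node infection-pressure
   bookkeeping, plus the two Monte-Carlo measurement procedures described
   below.
3. **Graphical (percolation) representation** (`graphical`): Poisson
   "points of cure" at rate `g_i` on each individual's time line and
   Poisson "arrows of infection" at rate `T[i, j]` between lines;
   infection at time `t` from seed set `A` is existence of a
   time-respecting path blocked by cure points.  Reversing time maps a
   realisation to one of the transposed network while preserving path
   existence, which yields the duality identity *per realisation*, not
   merely in distribution.

The headline relationship verified by `analysis` is that quasi-invasion
from any subset `A` of `T` equals the QSD probability that `A` contains
an infectious individual on the transpose `T^T`; for undirected networks
the two quantifiers coincide node by node, and globally the mean
single-seed invasion probability equals the expected fraction of the
population infected in the QSD.

## Parameters and defaults

- **Recovery rate**: generators default to `g_i = 1` for all individuals
  (rates are then expressed in units of the mean infectious period).
- **Exact-computation cap**: `n <= 12` (32,767 transient states) with an
  explicit override.  Dense eigensolves are used up to 127 states (n <= 7),
  ARPACK at machine tolerance above; both paths must agree, and residuals
  of both eigenvector equations are verified below `1e-10` (max-norm)
  before a result is returned.
- **Time-average estimator**: default burn-in is 90% of the event budget;
  standard errors by batch means over 50 equal-event batches, because
  consecutive inter-event intervals are strongly correlated.
- **Dichotomised invasion estimator**: default censoring threshold of 500
  infection events; binomial standard errors.  The histogram of infection
  events per replicate is always attached, with a dichotomy score (the
  fraction of replicates landing in the middle third of `[0, c]`): a
  score above ~0.05 means early extinctions and persistent runs did not
  separate and the censored fraction should not be read as an invasion
  probability.
- **Random-network generator**: a directed Hamiltonian cycle through a
  random permutation guarantees strong connectivity; independent extra
  edges with a configurable probability; weights uniform on (0.1, 1) by
  default.  Fixed seeds reproduce networks bit-exactly.
- **Reproducibility of estimators**: one master seed; replicate `k` uses
  `SeedSequence(master, spawn_key=(k,))`, so replicate sets are
  order-independent and extendable without disturbing earlier replicates.

## Conditioning on non-extinction: resurrection sampling

The time-average estimator measures the proportion of simulated time each
node spends infectious after burn-in, which estimates the QSD marginal
only conditional on the chain not being absorbed.  On large supercritical
networks extinction is astronomically rare and the plain time average
suffices.  On small networks the chain dies constantly — a 3-node
complete network with edge rate 5 and unit recovery has decay parameter
`alpha = 0.040` and a mean lifetime of roughly 130 events — and no run
long enough for a meaningful average survives.  The estimator therefore
defaults to *resurrection sampling*: when the infection dies out, the
chain restarts instantly (zero simulated time elapses) from a
configuration drawn from the time-weighted record of its own past.  The
occupation measure of such a self-resurrecting chain converges to the
QSD, a standard device for simulating quasi-stationary distributions of
absorbing chains.  For populations up to 32 the record is exact
(occupation time per visited configuration, stored by bitmask); above
that a fixed-size time-weighted reservoir of snapshots is used, which is
coarser but only exercised on networks where extinction is rare anyway.
A strict mode (`on_extinction='rerun'`) instead discards any attempt that
dies before burn-in and reruns with a fresh seed, raising a diagnostic
error after repeated failures — appropriate when the user wants to be
told, rather than have the estimator work around, that quasi-stationarity
is not practically observable.

Calibration on the 2-node closed-form network (40 independent estimates):
mean standardised error 0.13, standard deviation 0.89, i.e. negligible
bias and slightly conservative batch-means standard errors.

## Numerical choices

- State encoding: bit `i` of the state index set iff node `i` is
  infectious; transient state with mask `m` occupies row `m - 1`.
- Transient probabilities use the action of the matrix exponential
  (`expm_multiply`) on the indicator of target states rather than a full
  `expm`, and are clipped to `[0, 1]` against roundoff.
- Left-eigenvector sign is fixed by forcing a nonnegative sum before
  normalising to total mass 1; the right eigenvector is scaled by its
  all-infected entry.
- The simulation engine rebuilds its cached rate totals every 4096 events
  to purge floating-point drift from incremental updates.
- Graphical realisations store explicit event lists so the identical
  randomness can be swept forward and backward; simultaneous event times
  have probability zero, but ties arising in floating point are broken by
  a stable global order index, negated under time reversal so both sweeps
  see mirrored orders.  Duality at an interior time `t` restricts the
  realisation to `(0, t]` before reversing about `t`.
- Arrows pointing at an already-infectious node are no-ops in the sweep;
  this matches the master equation (infection applies to susceptibles)
  and does not change reachability.

## What the generators emulate — and what they do not

The built-in generators cover the study conditions used throughout the
tests: homogeneously weighted non-periodic square lattices, complete
networks, and random strongly connected directed networks with uniform
weights and (optionally) heterogeneous recovery rates.  They produce
small, dense or regular graphs suitable for exact verification.  They do
not attempt to reproduce realistic epidemic contact structure — degree
heavy tails, clustering, spatial correlation, or transmission weights
spanning orders of magnitude.  Passing tests therefore demonstrate the
correctness of the machinery (exact identities hold to solver precision;
estimators are consistent with the master equation within sampling
error), not the practical relevance of the QSD on any particular
real-world network; the latter must be judged per network via the decay
parameter and the dichotomy diagnostic.  Real networks are supplied as
edge-list or adjacency text files with per-node recovery tables; the
largest strongly connected component can be extracted with
`largest_scc`, since all theoretical guarantees require strong
connectivity.

## Known limitations

- The censored-fraction invasion estimator is biased low by a factor of
  roughly `exp(-alpha * T(c))`, where `T(c)` is the time needed for `c`
  infection events: some genuinely invaded runs die before censoring.
  The bias is negligible exactly when the survival curve has a clean
  plateau (`alpha` tiny relative to the event rate) and material
  otherwise — on a 3-node network with `alpha = 0.04`, no threshold
  gives an unbiased estimate.  The dichotomy score flags the grossly
  separated failures but cannot detect a slow plateau decay by itself;
  comparing against the exact decay parameter (available up to the cap)
  is the reliable check.
- Exact computations scale as `2^N` and stop at the configured cap;
  larger networks are served only by the simulation estimators.
- The time-average estimator's batch-means standard errors assume the
  batch length exceeds the mixing time; for very short runs they can be
  optimistic (`n_batches` is configurable).
- Resurrection sampling has a transient bias that decays as the history
  accumulates; burn-in should remain a large fraction of the budget on
  heavily-resurrecting (small) networks.

## Problem sizes in the test suite

Exact identities are verified on networks of 2–6 nodes (up to 63 states;
hundreds of random draws), duality on 10^4 sampled realisations,
simulator checks with 10^4–10^5 replicates, and estimator checks with
10^5–10^6 events — sizes at which the full suite completes in well under
a minute while keeping Monte-Carlo standard errors a factor of several
below the effects being tested.
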