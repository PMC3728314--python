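# sisqsd

**Endemic prevalence, invasion probability, and duality for Markovian SIS
dynamics on finite contact networks.**

For susceptible–infectious–susceptible (SIS) dynamics on a finite network
there is no true endemic steady state — extinction is certain in the long
run — and no obvious definition of "the probability that an outbreak
invades".  Both notions become exact on any strongly connected weighted
directed network `T` (edge `T[i,j]` = rate at which `i` infects `j`;
recovery rates `g`):

- **Endemic prevalence** is read from the quasi-stationary distribution
  (QSD) `nu`, the law of the process conditioned on non-extinction: the
  left Perron eigenvector of the sub-generator `Q` over the `2^N - 1`
  transient states, `nu Q = -alpha nu`.  The decay parameter `alpha` is
  the rate at which survival probability decays once the QSD is reached.
- **Invasion probability** from an initial infected set `A` is the limit
  of the ratio of survival probabilities, started from `A` versus started
  from everyone infected.  It equals `w(A)`, the entry of the right
  Perron eigenvector `Q w = -alpha w` normalised to `w = 1` at the
  all-infected state.

The package's central identity, which it verifies exactly and by
simulation, links the two across network transposition:

```
P(quasi-invasion from A on T)  =  P(some member of A infectious in the QSD of T^T)
```

so for undirected networks invasion probability and endemic prevalence
coincide individual by individual, and the population-mean single-seed
invasion probability equals the expected fraction infected in the QSD.
The proof device — the Harris graphical representation, where infection
travels along Poisson "arrows" between time lines and is blocked by
Poisson "points of cure", and time reversal maps realisations of `T` to
realisations of `T^T` — is itself implemented and checked realisation by
realisation.

## What's inside

| module | contents |
| --- | --- |
| `sisqsd.networks` | `ContactNetwork` (sparse rate matrix + recovery vector + labels), transpose, strong-connectivity and largest-SCC analysis, lattice/complete/random generators, edge-list and adjacency text I/O |
| `sisqsd.exact` | sub-generator assembly, QSD / decay parameter / invasion vector via dense or ARPACK eigensolves, transient event probabilities via the matrix-exponential action, survival ratios and conditioned prevalence |
| `sisqsd.gillespie` | direct event-driven simulation; time-average prevalence estimator (with resurrection sampling to condition on non-extinction); dichotomised-persistence invasion estimator with histogram diagnostic; empirical survival curves |
| `sisqsd.graphical` | sampling of graphical realisations, reachability sweeps, time reversal, per-realisation duality checks |
| `sisqsd.analysis` | exact prevalence–invasion verification, transpose-invariance checks, paired invasion-vs-prevalence experiments under a transmissibility multiplier |
| `sisqsd.cli` | thin `sisqsd` command-line front end over the above |

## Worked example

```python
from sisqsd import (build_subgenerator, complete_network, compute_qsd,
                    invasion_probability_exact, qsd_event_probability)

net = complete_network(2, beta=1.0)          # two individuals, rate 1 each way
res = compute_qsd(build_subgenerator(net))
print(res.alpha)                             # 0.5857864376269049
print(qsd_event_probability(res, {0}))       # 0.7071067811865476
print(invasion_probability_exact(res, {0}))  # 0.7071067811865475
```

The three-state master equation solves in closed form: the decay
parameter is `2 - sqrt(2)` and both the marginal prevalence of a node in
the QSD and the probability of invasion from that node are `sqrt(2)/2` —
equal, as the identity demands on an undirected network.

Longer narrative scripts live in `examples/`, one per capability
(`closed_form_two_node.py`, `prevalence_invasion_identity.py`,
`duality_realisation.py`, `estimators_vs_exact.py`,
`paired_experiment.py`).  For instance
`python examples/prevalence_invasion_identity.py` prints the invasion
probability on a random directed 5-node network and the QSD prevalence on
its transpose for all 31 subsets (agreeing to `~6e-15`), and
`python examples/estimators_vs_exact.py` compares Gillespie estimates
with master-equation values:

```
QSD marginal prevalence, complete network of 3, beta=5
node   time-average   +/- SE     exact (eigenvector)
  0    0.9022       0.0023    0.900241
  1    0.8991       0.0017    0.900241
  2    0.9002       0.0019    0.900241
```

A thin CLI mirrors the library:

```sh
sisqsd net generate --kind complete --n 3 --beta 2 --out net.tsv
sisqsd exact qsd --net net.tsv
sisqsd verify relationship --net net.tsv --scope all
```

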