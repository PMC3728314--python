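"""Exact quantifiers on the smallest nontrivial network.

Two individuals infecting each other at rate 1, each recovering at rate 1.
The 3-state sub-generator solves in closed form: the decay parameter is
2 - sqrt(2) and both the marginal quasi-prevalence and the single-seed
invasion probability are sqrt(2)/2.
"""

import math

from sisqsd import (
    build_subgenerator,
    complete_network,
    compute_qsd,
    invasion_probability_exact,
    qsd_event_probability,
)

net = complete_network(2, beta=1.0)
res = compute_qsd(build_subgenerator(net))

print(f"decay parameter alpha      : {res.alpha:.12f}   (2 - sqrt(2) = {2 - math.sqrt(2):.12f})")
print(f"QSD marginal prevalence p_0: {qsd_event_probability(res, {0}):.12f}")
print(f"invasion probability w({{0}}): {invasion_probability_exact(res, {0}):.12f}")
print(f"sqrt(2)/2                  : {math.sqrt(2) / 2:.12f}")
print()
print("alpha is the exponential rate at which survival decays once the")
print("quasi-stationary distribution is reached; prevalence and invasion")
print("coincide because the network is undirected (self-dual).")
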