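"""Per-realisation duality in the graphical representation.

A realisation places Poisson cure points on each individual's time line
and Poisson infection arrows between lines; infection spreads along
time-respecting paths blocked by cures.  Turning one fixed realisation
upside down (and reversing arrows) yields a realisation for the
transposed network in which path existence is preserved exactly — not
just in distribution.
"""

import numpy as np

from sisqsd import duality_check, random_strongly_connected_network, sample_realisation

net = random_strongly_connected_network(4, 0.4, (0.2, 1.0), seed=3)
rng = np.random.default_rng(0)

checked = agreed = 0
for _ in range(2000):
    real = sample_realisation(net, t_max=2.0, seed=rng)
    for a in range(4):
        for w in range(4):
            fwd, bwd, equal = duality_check(real, {a}, {w}, t=2.0)
            checked += 1
            agreed += equal

print(f"realisations sampled : 2000")
print(f"(A, W) pairs checked : {checked}")
print(f"indicators agreeing  : {agreed}  ({100.0 * agreed / checked:.1f}%)")
print()
print("Every forward indicator (path from A to W) equals its time-reversed")
print("counterpart (path from W back to A on the reversed diagram): the")
print("agreement is a deterministic identity, realisation by realisation.")
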