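"""Paired measurement of invasion probability and endemic prevalence.

Varying a scalar multiplier of the rate matrix emulates infectious agents
of different transmissibility on one population.  For each multiplier the
invasion probability from a seed node is estimated by dichotomised
persistence (fraction of outbreaks reaching a censoring threshold of
infection events) and the node's endemic quasi-prevalence by the
time-average estimator on the transposed network (the same network here,
since it is undirected).  The identity between the two quantifiers puts
the pairs on the diagonal.
"""

from sisqsd import complete_network, paired_quantifier_experiment

net = complete_network(5, beta=5.0)
rows = paired_quantifier_experiment(
    net,
    seed_node=0,
    multipliers=[0.3, 0.6, 1.0],
    n_reps=2000,
    threshold=50,
    total_events=100_000,
    seed=11,
)

print("multiplier   invasion +/- SE      prevalence +/- SE    reliable")
for r in rows:
    print(
        f"  {r['multiplier']:.1f}       {r['invasion']:.4f} +/- {r['invasion_se']:.4f}"
        f"   {r['prevalence']:.4f} +/- {r['prevalence_se']:.4f}    {r['reliable']}"
    )
print()
print("Each row pairs two independent Monte-Carlo measurements of what the")
print("theory says is the same number; 'reliable' reports the dichotomy")
print("diagnostic (separation of early extinctions from persistent runs).")
print("At the smallest multiplier the invasion estimate falls visibly short")
print("of the prevalence: extinction from the endemic state is still fast")
print("enough (larger decay parameter) that some genuinely invaded runs die")
print("before the censoring threshold - the censored fraction is biased low")
print("whenever the survival curve has no clean plateau.")
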