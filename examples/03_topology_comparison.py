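"""Ranking alternative species-tree topologies by Dollo parsimony cost.

Simulates domain evolution on a 16-leaf tree (per-branch loss
probability 0.1, 1000 domains) and compares the generating topology
against an SPR-perturbed alternative: the true topology needs fewer
loss events to explain the same presence/absence matrix.
"""

from domevol import compare_topologies
from domevol.simulate import (
    SimConfig,
    random_tree,
    simulate_domain_evolution,
    spr_perturb,
)

tree = random_tree(16, seed=7)
truth = simulate_domain_evolution(
    SimConfig(tree=tree, n_domains=1000, loss_prob=0.1, seed=8)
)
matrix = truth.matrix()
alternative = spr_perturb(tree, seed=9)

ranking = compare_topologies([tree, alternative], matrix)
for candidate, cost in ranking:
    tag = "generating" if candidate is tree else "SPR-perturbed"
    print(f"cost {cost}: {tag} topology")
print(f"true event count in the simulation: {truth.total_events}")
# The generating tree ranks first, and its inferred cost never exceeds
# the true number of events (the truth is itself a feasible single-gain
# history) — the same cost comparison used to weigh competing hypotheses
# about deep animal phylogeny.
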