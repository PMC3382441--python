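"""Infer a species tree from gene trees by hill climbing (kNNIST).

30 clean simulated families from a known 8-taxon species tree; a 20-restart
hill climb at k=0 should rediscover the true unrooted species topology as a
cost-co-optimal tree.
"""

from dlrecon import SearchConfig, UnrootedGeneTree, hill_climb
from dlrecon.search import nested_newick
from dlrecon.simulate import SimulationConfig, random_species_tree, \
    simulate_dataset

S = random_species_tree(8, seed=21)
data = simulate_dataset(S, 30, SimulationConfig(), seed=21)
genes = [rec.true_unrooted for rec in data]

res = hill_climb(genes, S.labels, SearchConfig(runs=20, seed=5))

print("true species tree :", S.newick())
print(f"best total cost   : {res.best_cost:g} "
      f"({res.evaluations} candidate evaluations)")
for nwk in res.best_newicks():
    print("co-optimal tree   :", nwk)

truth = UnrootedGeneTree.from_nested(S.to_nested()).topology_key()
hit = any(UnrootedGeneTree.from_nested(t).topology_key() == truth
          for t in res.best_trees)
print("true unrooted shape recovered:", hit)
# Rootings of the same unrooted shape tie on the duplication-loss
# objective when the data are clean, so co-optimal trees are expected.
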