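"""Optimally root an unrooted gene tree against a species tree.

The displaced quartet bc|ad disagrees with the species tree ((a,b),(c,d));
reconciliation charges its best rooting 1 duplication + 4 losses.
"""

from dlrecon import SpeciesTree, UnrootedGeneTree, optimal_edges, \
    reconciliation_cost

S = SpeciesTree.from_newick("((a,b),(c,d));")

for newick in ["((a,b),(c,d));", "((b,c),(a,d));"]:
    G = UnrootedGeneTree.from_newick(newick)
    state = optimal_edges(G, S)
    rooting = state.canonical_rooting()
    cost = reconciliation_cost(rooting, S)
    print(f"{newick:22s} optimal cost {state.sigma:g} "
          f"({cost.dups} dup, {cost.losses} loss), "
          f"{len(state.minset)} optimal edge(s), rooted: {rooting.newick()}")

# The congruent quartet roots at its center for free; the displaced one
# cannot do better than 5 wherever it is rooted.
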