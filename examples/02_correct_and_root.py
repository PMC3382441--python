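"""Simultaneously error-correct and root a gene tree (k-NNI search).

One NNI on a weak edge turns bc|ad back into the congruent ab|cd, dropping
the cost from 5 to 0 - the tree had an error.
"""

from dlrecon import CorrectionConfig, SpeciesTree, UnrootedGeneTree, \
    corrected_cost

S = SpeciesTree.from_newick("((a,b),(c,d));")
# the two root-adjacent lengths merge additively when the degree-2 root is
# suppressed, so the central edge of this quartet gets length 0.02
G = UnrootedGeneTree.from_newick("((b:1,c:1):0.01,(a:1,d:1):0.01);")

for k in (0, 1):
    r = corrected_cost(G, S, CorrectionConfig(k=k, omega=0.05))
    print(f"k={k}: cost {r.cost:g} (before {r.cost_before:g}), "
          f"{len(r.moves)} NNI(s), errors_found={r.errors_found}, "
          f"corrected: {r.corrected_newick} rooted: {r.rooted_newick}")

# With k=1 the single weak internal edge (length 0.01 < omega) is the only
# NNI center tried; its interchange recovers the congruent topology.
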