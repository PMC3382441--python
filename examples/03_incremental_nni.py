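"""Constant-time NNI bookkeeping on a random gene tree.

A random walk of NNI moves, with the reconciliation state (arc labels,
optimal-edge set, optimal cost) maintained incrementally and checked
against a from-scratch brute force at the end.
"""

import random

from dlrecon import (apply_nni, brute_force_optimal, make_frame,
                     optimal_edges, undo_nni)
from dlrecon.simulate import SimulationConfig, evolve_gene_tree, \
    random_species_tree

rng = random.Random(4)
S = random_species_tree(8, rng)
_, G = evolve_gene_tree(S, SimulationConfig(dup_rate=0.2), rng)

state = optimal_edges(G, S)
print(f"gene tree with {G.n_leaves()} leaves, start cost {state.sigma:g}")

tokens = []
for step in range(10):
    edges = G.internal_edges()
    frame = make_frame(G, edges[rng.randrange(len(edges))], rng.randrange(2))
    tokens.append(apply_nni(state, frame))
    print(f"step {step + 1}: cost {state.sigma:g}, "
          f"|Min|={len(state.minset)}")

bf = brute_force_optimal(G, S)
print("matches brute force:", state.sigma == bf.sigma
      and state.minset == bf.minset)

for t in reversed(tokens):
    undo_nni(state, t)
print(f"after undoing all moves the cost is {state.sigma:g} again")
print("lemma-case frequencies:", dict(state.case_counts))
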