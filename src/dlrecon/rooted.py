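"""Classical rooted gene tree / species tree reconciliation.

Given a rooted binary gene tree G and a rooted binary species tree S, the
lca-mapping M sends every gene leaf to the species leaf with the same label
and every internal node to the least common ancestor of its children's
images.  An internal node v with children w1, w2 contributes

* a duplication when M(w1) and M(w2) are comparable
  (kappa_D(v) = D(M(w1), M(w2)) in {0, 1}), and
* kappa_L(v) = L(M(w1), M(w2)) losses, the number of species lineages
  branching off the path between the two images.

sigma_D = sum kappa_D and sigma_L = sum kappa_L are the minimal duplication
and loss counts of any embedding of G into S; the weighted mutation cost is
alpha * sigma_D + beta * sigma_L.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .trees import RootedGeneTree, SpeciesTree, TreeError

__all__ = ["CostWeights", "NodeCostRecord", "ReconciliationCost",
           "lca_mapping", "node_costs", "reconciliation_cost",
           "node_cost_table"]


@dataclass(frozen=True)
class CostWeights:
    """Weights of the mutation cost: ``alpha`` per duplication, ``beta`` per
    loss.  Both must be positive."""

    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("cost weights must be positive")

    def total(self, dups: int, losses: int) -> float:
        return self.alpha * dups + self.beta * losses


@dataclass(frozen=True)
class NodeCostRecord:
    """Per-node contributions: ``dup`` is kappa_D (0/1 duplication flag),
    ``losses`` is kappa_L."""

    dup: int
    losses: int


@dataclass(frozen=True)
class ReconciliationCost:
    dups: int
    losses: int
    total: float


def lca_mapping(g: RootedGeneTree, s: SpeciesTree) -> list[int]:
    """The lca-mapping M as a list indexed by gene-tree node id."""
    m: list[Optional[int]] = [None] * g.n_nodes
    for v in g.postorder():
        if g.is_leaf(v):
            lab = g.leaf_label[v]
            try:
                m[v] = s.label_to_leaf[lab]
            except KeyError:
                raise TreeError(f"gene leaf label {lab!r} absent from species tree")
        else:
            a, b = g.children[v]
            m[v] = s.lca(m[a], m[b])
    return m  # type: ignore[return-value]


def node_costs(g: RootedGeneTree, m: list[int], s: SpeciesTree) -> dict[int, NodeCostRecord]:
    """kappa_D and kappa_L for every gene-tree node (leaves contribute 0)."""
    out: dict[int, NodeCostRecord] = {}
    for v in range(g.n_nodes):
        if g.is_leaf(v):
            out[v] = NodeCostRecord(0, 0)
        else:
            a, b = g.children[v]
            out[v] = NodeCostRecord(s.comparable(m[a], m[b]),
                                    s.loss_count(m[a], m[b]))
    return out


def reconciliation_cost(g: RootedGeneTree, s: SpeciesTree,
                        weights: CostWeights = CostWeights()) -> ReconciliationCost:
    """Minimal duplication/loss counts and the weighted mutation cost."""
    m = lca_mapping(g, s)
    dups = losses = 0
    for v in g.internal_nodes():
        a, b = g.children[v]
        dups += s.comparable(m[a], m[b])
        losses += s.loss_count(m[a], m[b])
    return ReconciliationCost(dups, losses, weights.total(dups, losses))


def node_cost_table(g: RootedGeneTree, s: SpeciesTree) -> list[tuple[int, str, int, int]]:
    """Per-node report rows: (post-order index, mapped cluster name,
    kappa_D, kappa_L)."""
    m = lca_mapping(g, s)
    recs = node_costs(g, m, s)
    return [(i, s.name(m[v]), recs[v].dup, recs[v].losses)
            for i, v in enumerate(g.postorder())]
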