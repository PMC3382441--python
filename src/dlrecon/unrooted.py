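"""Unrooted reconciliation: optimal rootings of a gene tree against a species tree.

Every edge e of an unrooted gene tree G induces a rooting G_e (subdivide e
with a new root).  The machinery here finds the set Min_G of edges whose
rootings minimize the weighted mutation cost, together with that minimum,
in time O(max(|G|, |S|)).

The device is the doubled directed tree: each undirected edge {v, w} becomes
the two arcs <v, w> and <w, v>, and the arc <v, w> is labeled by the lca of
the species below the leaves on v's side.  A leaf arc carries the leaf's
species; an internal arc <v, w3> carries the join of the labels of the two
arcs entering v from its other neighbors.  With the species tree restricted
to the lca of the gene tree's labels (so that every rooting maps its root to
the restricted top; the cost is unchanged by this restriction), an edge is
*symmetric* when zero or two of its arc labels equal the top and *asymmetric*
when exactly one does, and each internal node's star of three edges falls
into one of five types S1-S5 by the placement of top labels.  The optimal
edge set is characterized structurally (M1/M2) and non-top arcs point toward
it; here the per-edge costs themselves are obtained by a rerooting sweep over
the arcs, which yields Min_G and the optimum directly.

``brute_force_optimal`` roots G at every edge and reconciles from scratch;
it shares no code path with the sweep and serves as the independent oracle.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .rooted import CostWeights, ReconciliationCost, reconciliation_cost
from .trees import Edge, RootedGeneTree, SpeciesTree, TreeError, UnrootedGeneTree

__all__ = [
    "ReconciliationState", "BruteForceResult",
    "compute_labels", "classify_star", "edge_is_symmetric",
    "optimal_edges", "brute_force_optimal", "check_c1",
]

Arc = tuple[int, int]

STAR_TYPES = {
    (3, 3): "S4",
    (2, 3): "S5",
    (1, 3): "S3",
    (1, 2): "S1",
    (0, 2): "S2",
}


class StarClassificationError(RuntimeError):
    """A produced labeling matches none of the five star types; indicates a
    labeling bug (the taxonomy is provably total for valid inputs)."""


def _oriented_passes(g: UnrootedGeneTree, root: int):
    """Orient g away from ``root``: returns (order, parent_node, parent_edge)
    with ``order`` a list of nodes in pre-order."""
    parent_node: dict[int, Optional[int]] = {root: None}
    parent_edge: dict[int, Optional[Edge]] = {root: None}
    order = [root]
    stack = [root]
    while stack:
        v = stack.pop()
        for e in g.adj[v]:
            w = e.other(v)
            if w not in parent_node:
                parent_node[w] = v
                parent_edge[w] = e
                order.append(w)
                stack.append(w)
    return order, parent_node, parent_edge


def compute_labels(g: UnrootedGeneTree, s: SpeciesTree) -> tuple[dict[Arc, int], int]:
    """All 2|E| arc labels plus the top element (lca of the gene labels).

    Two linear passes: an inward (post-order) pass computes labels toward an
    arbitrary root, an outward (pre-order) pass the reverse arcs.
    """
    for lab in set(g.leaf_label.values()):
        if lab not in s.label_to_leaf:
            raise TreeError(f"gene leaf label {lab!r} absent from species tree")
    top = s.lca_of_labels(g.leaf_label.values())
    labels: dict[Arc, int] = {}
    root = g.nodes[0]
    order, parent_node, _ = _oriented_passes(g, root)

    # inward: label <v, parent(v)>
    for v in reversed(order):
        p = parent_node[v]
        if p is None:
            continue
        if g.is_leaf(v):
            labels[(v, p)] = s.label_to_leaf[g.leaf_label[v]]
        else:
            ns = [w for w, _ in g.neighbors(v) if w != p]
            labels[(v, p)] = s.lca(labels[(ns[0], v)], labels[(ns[1], v)])
    # outward: label <v, c> for every child c
    for v in order:
        if g.is_leaf(v):
            for w, _ in g.neighbors(v):
                labels[(v, w)] = s.label_to_leaf[g.leaf_label[v]]
            continue
        for c, _ in g.neighbors(v):
            if c == parent_node[v]:
                continue
            others = [labels[(w, v)] for w, _ in g.neighbors(v) if w != c]
            labels[(v, c)] = s.lca(others[0], others[1])
    return labels, top


def edge_is_symmetric(labels: dict[Arc, int], edge: Edge, top: int) -> bool:
    """Symmetric: zero or two arc labels equal the top; asymmetric: exactly one."""
    return ((labels[(edge.u, edge.v)] == top) +
            (labels[(edge.v, edge.u)] == top)) != 1

def classify_star(g: UnrootedGeneTree, labels: dict[Arc, int], center: int,
                  top: int) -> str:
    """Star type S1-S5 of an internal node by counting top labels on the
    three incoming and three outgoing arcs."""
    if g.is_leaf(center):
        raise ValueError("star center must be internal")
    inc = sum(labels[(w, center)] == top for w, _ in g.neighbors(center))
    out = sum(labels[(center, w)] == top for w, _ in g.neighbors(center))
    try:
        return STAR_TYPES[(inc, out)]
    except KeyError:
        raise StarClassificationError(
            f"star at node {center} has (incoming, outgoing) top counts "
            f"({inc}, {out}), matching none of S1-S5")


def check_c1(g: UnrootedGeneTree, labels: dict[Arc, int], top: int) -> bool:
    """Composition condition C1: any two S2 stars share a common edge."""
    centers = [v for v in g.adj
               if not g.is_leaf(v)
               and classify_star(g, labels, v, top) == "S2"]
    if len(centers) <= 1:
        return True
    if len(centers) > 2:
        return False
    a, b = centers
    return any(e.other(a) == b for e in g.adj[a])


def _node_contribution(g: UnrootedGeneTree, s: SpeciesTree,
                       labels: dict[Arc, int], v: int, away: int) -> tuple[int, int]:
    """(dup, loss) contribution of internal node v when its parent direction
    is the neighbor ``away``: D/L of the labels entering from the other two."""
    ns = [w for w, _ in g.neighbors(v) if w != away]
    b1, b2 = labels[(ns[0], v)], labels[(ns[1], v)]
    return s.comparable(b1, b2), s.loss_count(b1, b2)


def rooting_costs(g: UnrootedGeneTree, s: SpeciesTree,
                  labels: dict[Arc, int]) -> dict[int, tuple[int, int]]:
    """(duplications, losses) of the rooting at every edge, by a rerooting
    sweep: F<v,w> accumulates the contributions of the internal nodes on v's
    side oriented away from w; the rooting at {u, v} adds the root node's own
    D/L of the two arc labels."""
    root = g.nodes[0]
    order, parent_node, _ = _oriented_passes(g, root)
    F: dict[Arc, tuple[int, int]] = {}

    for v in reversed(order):  # inward
        p = parent_node[v]
        if p is None:
            continue
        if g.is_leaf(v):
            F[(v, p)] = (0, 0)
        else:
            d, l = _node_contribution(g, s, labels, v, p)
            for w, _ in g.neighbors(v):
                if w != p:
                    dd, ll = F[(w, v)]
                    d += dd
                    l += ll
            F[(v, p)] = (d, l)
    for v in order:  # outward
        for c, _ in g.neighbors(v):
            if c == parent_node[v]:
                continue
            if g.is_leaf(v):
                F[(v, c)] = (0, 0)
            else:
                d, l = _node_contribution(g, s, labels, v, c)
                for w, _ in g.neighbors(v):
                    if w != c:
                        dd, ll = F[(w, v)]
                        d += dd
                        l += ll
                F[(v, c)] = (d, l)

    out: dict[int, tuple[int, int]] = {}
    for e in g.edges:
        du, lu = F[(e.u, e.v)]
        dv, lv = F[(e.v, e.u)]
        rd = s.comparable(labels[(e.u, e.v)], labels[(e.v, e.u)])
        rl = s.loss_count(labels[(e.u, e.v)], labels[(e.v, e.u)])
        out[e.id] = (du + dv + rd, lu + lv + rl)
    return out


@dataclass
class ReconciliationState:
    """Labeling + optimal-edge set + optimal cost, maintained across NNIs.

    ``minset`` holds the Edge objects whose rootings attain ``sigma``;
    ``labels`` the current arc labels; ``top`` the restricted species-tree
    root (lca of the gene labels).  ``fallback_count`` counts incremental
    updates that had to fall back to a full recomputation (expected 0).
    """

    g: UnrootedGeneTree
    s: SpeciesTree
    weights: CostWeights
    labels: dict[Arc, int]
    top: int
    minset: set[Edge]
    sigma: float
    fallback_count: int = 0
    case_counts: Counter = field(default_factory=Counter)

    def edge_cost(self, edge: Edge) -> tuple[int, int]:
        """(dups, losses) of the rooting at ``edge``, recomputed from the
        current labels in O(|G|)."""
        d = self.s.comparable(self.labels[(edge.u, edge.v)],
                              self.labels[(edge.v, edge.u)])
        l = self.s.loss_count(self.labels[(edge.u, edge.v)],
                              self.labels[(edge.v, edge.u)])
        for endpoint in (edge.u, edge.v):
            stack = [(endpoint, edge)]
            while stack:
                v, came = stack.pop()
                if self.g.is_leaf(v):
                    continue
                dd, ll = _node_contribution(self.g, self.s, self.labels,
                                            v, came.other(v))
                d += dd
                l += ll
                for e in self.g.adj[v]:
                    if e is not came:
                        stack.append((e.other(v), e))
        return d, l

    def recompute(self) -> None:
        """Full recomputation of labels, Min_G and sigma from the tree."""
        self.labels, self.top = compute_labels(self.g, self.s)
        costs = rooting_costs(self.g, self.s, self.labels)
        totals = {eid: self.weights.total(*dl) for eid, dl in costs.items()}
        self.sigma = min(totals.values())
        self.minset = {e for e in self.g.edges if totals[e.id] == self.sigma}

    def canonical_min_edge(self) -> Edge:
        """Deterministic representative of Min_G: the edge with the
        lexicographically smallest incident leaf-label bipartition."""
        return min(self.minset, key=lambda e: (self.g.bipartition(e), e.id))

    def canonical_rooting(self) -> RootedGeneTree:
        return RootedGeneTree.from_rooting(self.g, self.canonical_min_edge())

    def star_type(self, center: int) -> str:
        return classify_star(self.g, self.labels, center, self.top)

    def edge_symmetric(self, edge: Edge) -> bool:
        return edge_is_symmetric(self.labels, edge, self.top)


def optimal_edges(g: UnrootedGeneTree, s: SpeciesTree,
                  weights: CostWeights = CostWeights()) -> ReconciliationState:
    """Min_G and the optimal weighted mutation cost over all rootings,
    in O(max(|G|, |S|))."""
    labels, top = compute_labels(g, s)
    costs = rooting_costs(g, s, labels)
    totals = {eid: weights.total(*dl) for eid, dl in costs.items()}
    sigma = min(totals.values())
    minset = {e for e in g.edges if totals[e.id] == sigma}
    return ReconciliationState(g=g, s=s, weights=weights, labels=labels,
                               top=top, minset=minset, sigma=sigma)


@dataclass
class BruteForceResult:
    costs: dict[int, ReconciliationCost]
    minset: set[Edge]
    sigma: float


def brute_force_optimal(g: UnrootedGeneTree, s: SpeciesTree,
                        weights: CostWeights = CostWeights()) -> BruteForceResult:
    """Testing oracle: root G at every edge and reconcile from scratch."""
    costs: dict[int, ReconciliationCost] = {}
    for e in g.edges:
        costs[e.id] = reconciliation_cost(RootedGeneTree.from_rooting(g, e),
                                          s, weights)
    sigma = min(c.total for c in costs.values())
    minset = {e for e in g.edges if costs[e.id].total == sigma}
    return BruteForceResult(costs, minset, sigma)
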