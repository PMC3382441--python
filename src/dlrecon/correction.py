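"""Simultaneous rooting and error correction over k-NNI neighborhoods.

``corrected_cost`` computes sigma_{alpha,beta,k}(S, G): the minimum of the
unrooted reconciliation cost over every gene tree reachable from G by at
most k NNI operations, optionally restricted to *weak* edges (length
strictly below a threshold omega).  The search is a depth-first enumeration
of NNI sequences driven by the constant-time incremental updates of the NNI
engine, applying each move in place and undoing it afterwards -- no tree is
ever copied during the search.  Eligibility follows edge identity: the five
edges of an NNI frame persist through the rewiring, and the center edge
keeps its length, so an edge that was weak in the input stays eligible along
every search path.

A gene tree "has errors" when some non-empty NNI sequence strictly improves
on the cost of the tree as given.  ``knnic_total`` aggregates the corrected
costs of a collection of gene trees against one species tree; ``filter_by_mu``
is the companion curation filter rejecting gene trees with more than mu weak
edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .nni import apply_nni, make_frame, undo_nni
from .rooted import CostWeights, reconciliation_cost
from .trees import Edge, SpeciesTree, TreeError, UnrootedGeneTree
from .unrooted import ReconciliationState, optimal_edges

__all__ = ["CorrectionConfig", "CorrectionResult", "weak_edges",
           "corrected_cost", "corrected_cost_value", "knnic_total",
           "filter_by_mu", "KnnicResult"]


@dataclass(frozen=True)
class CorrectionConfig:
    """Parameters of the correction search.

    k: maximum number of NNI operations (k = 0: plain unrooted
    reconciliation).  omega: weak-edge length threshold; when set, NNI
    centers are restricted to internal edges with length strictly below
    omega (edges without a length are never weak).  mu: maximum number of
    weak edges tolerated per gene tree by the curation filter.
    """

    k: int = 0
    omega: Optional[float] = None
    mu: Optional[int] = None
    weights: CostWeights = field(default_factory=CostWeights)

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if self.omega is not None and not self.omega >= 0:
            raise ValueError("omega must be a non-negative real")
        if self.mu is not None and self.mu < 1:
            raise ValueError("mu must be a positive integer")


@dataclass
class CorrectionResult:
    """Best cost over the (restricted) <=k-NNI neighborhood of one gene tree."""

    cost: float
    cost_before: float
    moves: list[tuple[int, int]]          # (edge id, variant) per NNI applied
    corrected_newick: str
    corrected_key: tuple
    min_size: int
    optimal_bipartition: tuple
    rooted_newick: str
    dups: int
    losses: int
    errors_found: bool


def weak_edges(g: UnrootedGeneTree, omega: float) -> list[Edge]:
    """Edges whose length is strictly smaller than omega; unmeasured edges
    are never weak."""
    return [e for e in g.edges if e.length is not None and e.length < omega]


def _eligible_centers(g: UnrootedGeneTree, config: CorrectionConfig) -> list[Edge]:
    internal = g.internal_edges()
    if config.omega is None:
        return internal
    weak = set(id(e) for e in weak_edges(g, config.omega))
    return [e for e in internal if id(e) in weak]


def _search(state: ReconciliationState, eligible: list[Edge], k: int,
            track_moves: bool):
    """DFS over NNI sequences of length <= k with in-place apply/undo.

    Returns (best_cost, best_moves | None).  Ties prefer the shorter
    sequence, then the lexicographically smallest canonical topology
    encoding of the corrected tree (computed lazily).
    """
    g = state.g
    best = {
        "cost": state.sigma,
        "len": 0,
        "key": g.topology_key() if track_moves else None,
        "moves": [],
    }
    path: list[tuple[int, int]] = []

    def consider():
        c, n = state.sigma, len(path)
        if c > best["cost"]:
            return
        if c < best["cost"] or n < best["len"]:
            best.update(cost=c, len=n,
                        key=g.topology_key() if track_moves else None,
                        moves=list(path))
            return
        if not track_moves or n > best["len"]:
            return
        key = g.topology_key()
        if key < best["key"]:
            best.update(cost=c, len=n, key=key, moves=list(path))

    def dfs(depth: int):
        for e0 in eligible:
            for variant in (0, 1):
                frame = make_frame(g, e0, variant)
                token = apply_nni(state, frame)
                path.append((e0.id, variant))
                consider()
                if depth + 1 < k:
                    dfs(depth + 1)
                path.pop()
                undo_nni(state, token)

    if k > 0:
        dfs(0)
    return best["cost"], best["moves"]


def corrected_cost_value(g: UnrootedGeneTree, s: SpeciesTree,
                         config: CorrectionConfig) -> float:
    """sigma_{alpha,beta,k}(S, G) alone, without report assembly (used in the
    inner loop of the species-tree search)."""
    state = optimal_edges(g, s, config.weights)
    if config.k == 0:
        return state.sigma
    eligible = _eligible_centers(g, config)
    cost, _ = _search(state, eligible, config.k, track_moves=False)
    return cost


def corrected_cost(g: UnrootedGeneTree, s: SpeciesTree,
                   config: CorrectionConfig) -> CorrectionResult:
    """Exact minimum cost over the <=k-NNI neighborhood, with the corrected
    topology, the applied move sequence and the optimal rooting."""
    state = optimal_edges(g, s, config.weights)
    cost_before = state.sigma
    eligible = _eligible_centers(g, config)
    cost, moves = _search(state, eligible, config.k, track_moves=True)

    # replay the best sequence to report the corrected tree, then restore
    tokens = []
    for eid, variant in moves:
        frame = make_frame(g, g.edges[eid], variant)
        tokens.append(apply_nni(state, frame))

    corrected_newick = g.newick()
    corrected_key = g.topology_key()
    min_size = len(state.minset)
    opt_edge = state.canonical_min_edge()
    opt_bip = g.bipartition(opt_edge)
    rooting = state.canonical_rooting()
    rooted_newick = rooting.newick()
    rc = reconciliation_cost(rooting, s, config.weights)

    for token in reversed(tokens):
        undo_nni(state, token)

    return CorrectionResult(
        cost=cost, cost_before=cost_before, moves=moves,
        corrected_newick=corrected_newick, corrected_key=corrected_key,
        min_size=min_size, optimal_bipartition=opt_bip,
        rooted_newick=rooted_newick, dups=rc.dups, losses=rc.losses,
        errors_found=cost < cost_before)


@dataclass
class KnnicResult:
    total: float
    per_tree: list[CorrectionResult]


def knnic_total(gene_trees: Sequence[UnrootedGeneTree], s: SpeciesTree,
                config: CorrectionConfig) -> KnnicResult:
    """Total corrected cost of a gene-tree collection against one species
    tree (the kNNIC objective), with per-tree results retained."""
    per: list[CorrectionResult] = []
    for idx, g in enumerate(gene_trees):
        try:
            per.append(corrected_cost(g, s, config))
        except TreeError as exc:
            raise TreeError(f"gene tree #{idx}: {exc}") from exc
    return KnnicResult(total=sum(r.cost for r in per), per_tree=per)


def filter_by_mu(gene_trees: Sequence[UnrootedGeneTree], omega: float,
                 mu: int) -> tuple[list[UnrootedGeneTree], list[UnrootedGeneTree]]:
    """Partition gene trees into (accepted, rejected): a tree is rejected iff
    its weak-edge count exceeds mu."""
    if mu < 1:
        raise ValueError("mu must be a positive integer")
    accepted, rejected = [], []
    for g in gene_trees:
        (accepted if len(weak_edges(g, omega)) <= mu else rejected).append(g)
    return accepted, rejected
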