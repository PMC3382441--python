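"""Hill-climbing species-tree (supertree) search under corrected costs.

The kNNIST objective: given unrooted gene trees, find the rooted species
tree minimizing the total error-corrected reconciliation cost
sum_G sigma_{alpha,beta,k}(S, G).  Exact optimization is presumed hard (the
uncorrected gene-duplication problem already is), so the search is a
randomized-restart hill climb: start from a random rooted topology, move to
the best strictly-improving neighbor, stop at a local optimum.

The default neighborhood couples rooted-NNI rearrangements with rerooting
moves (rooting matters: the objective is defined against a *rooted* species
tree); an SPR mode widens the neighborhood for harder instances.  Candidate
trees are handled as nested label tuples in a canonical (sorted) form, which
doubles as the memoization key, so no candidate is ever evaluated twice in a
search.  With a fixed seed the whole search is reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .correction import (CorrectionConfig, corrected_cost_value,
                         filter_by_mu, knnic_total)
from .trees import RootedGeneTree, SpeciesTree, TreeError, UnrootedGeneTree

__all__ = ["SearchConfig", "SearchResult", "hill_climb", "total_cost_of_tree",
           "random_rooted_topology", "nested_newick"]

Nested = object  # a leaf label (str) or a pair of Nested


# ---------------------------------------------------------------------------
# Nested-tuple topology helpers
# ---------------------------------------------------------------------------

def _ser(t) -> str:
    if isinstance(t, str):
        return t
    return f"({_ser(t[0])},{_ser(t[1])})"


def nested_newick(t) -> str:
    return _ser(t) + ";"


def canonical(t):
    """Order-normalized form: children sorted by serialization; equal
    canonical forms iff the rooted topologies are label-isomorphic."""
    if isinstance(t, str):
        return t
    a, b = canonical(t[0]), canonical(t[1])
    return (a, b) if _ser(a) <= _ser(b) else (b, a)


def _leaves(t) -> list[str]:
    if isinstance(t, str):
        return [t]
    return _leaves(t[0]) + _leaves(t[1])


def random_rooted_topology(labels: Sequence[str], rng: random.Random):
    """Uniform random rooted binary topology by sequential leaf insertion:
    each new leaf subdivides a uniformly chosen edge (including the root
    edge)."""
    labs = list(labels)
    if len(labs) < 2:
        raise TreeError("need at least 2 species")
    t = labs[0]

    def count(n) -> int:
        return 1 if isinstance(n, str) else 1 + count(n[0]) + count(n[1])

    def insert_at(n, idx: int, leaf: str):
        # pre-order position idx: attach the leaf above that node
        if idx == 0:
            return (n, leaf), -1
        if isinstance(n, str):
            return n, idx - 1  # leaf consumed one pre-order position
        left, rem = insert_at(n[0], idx - 1, leaf)
        if rem < 0:
            return (left, n[1]), -1
        right, rem = insert_at(n[1], rem, leaf)
        return (n[0], right), rem

    for leaf in labs[1:]:
        pos = rng.randrange(count(t))
        t, rem = insert_at(t, pos, leaf)
        assert rem < 0
    return t


def _rooted_nni_neighbors(t) -> list:
    """All rooted-NNI rearrangements: across each internal edge, swap the
    child's child with the child's sibling."""
    out: list = []

    def rec(node, rebuild: Callable):
        if isinstance(node, str):
            return
        l, r = node
        if not isinstance(l, str):
            l1, l2 = l
            out.append(rebuild(((r, l2), l1)))
            out.append(rebuild(((l1, r), l2)))
        if not isinstance(r, str):
            r1, r2 = r
            out.append(rebuild((r1, (l, r2))))
            out.append(rebuild((r2, (r1, l))))
        rec(l, lambda nl: rebuild((nl, r)))
        rec(r, lambda nr: rebuild((l, nr)))

    rec(t, lambda n: n)
    return out


def _rerootings(t) -> list:
    """All rootings of the unrooted shape of t (one per unrooted edge)."""
    leaves = _leaves(t)
    if len(leaves) < 3:
        return [t]
    g = UnrootedGeneTree.from_nested(t)
    return [RootedGeneTree.from_rooting(g, e).to_nested() for e in g.edges]


def _regraft_everywhere(host, sub) -> list:
    out: list = []

    def rec(node, rebuild: Callable):
        out.append(rebuild((sub, node)))
        if not isinstance(node, str):
            l, r = node
            rec(l, lambda nl: rebuild((nl, r)))
            rec(r, lambda nr: rebuild((l, nr)))

    rec(host, lambda n: n)
    return out


def _spr_neighbors(t) -> list:
    """Rooted SPR: prune any subtree and regraft it on any edge of the rest."""
    out: list = []

    def rec(node, context: Callable):
        if isinstance(node, str):
            return
        l, r = node
        out.extend(_regraft_everywhere(context(r), l))
        out.extend(_regraft_everywhere(context(l), r))
        rec(l, lambda n: context((n, r)))
        rec(r, lambda n: context((l, n)))

    rec(t, lambda n: n)
    return out


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchConfig:
    """Hill-climb parameters: ``runs`` random restarts from seeded random
    start trees; ``moves`` is ``"nni"`` (rooted NNI + rerooting, default) or
    ``"spr"`` (adds subtree prune-regraft); ``correction`` carries k, omega,
    mu and the cost weights; ``max_steps`` caps one run (strict descent
    terminates long before in practice)."""

    runs: int = 20
    seed: int = 0
    moves: str = "nni"
    correction: CorrectionConfig = field(default_factory=CorrectionConfig)
    max_steps: int = 10_000

    def __post_init__(self):
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.moves not in ("nni", "spr"):
            raise ValueError("moves must be 'nni' or 'spr'")


@dataclass
class SearchResult:
    best_cost: float
    best_trees: list          # canonical nested tuples, co-optimal finals
    ranking: list             # (cost, canonical nested) distinct finals, sorted
    trajectories: list        # per run: list of (canonical nested, cost)
    n_accepted: int
    n_rejected: int
    evaluations: int

    def best_newicks(self) -> list[str]:
        return [nested_newick(t) for t in self.best_trees]


def _neighbor_set(t, moves: str) -> list:
    nbrs = _rooted_nni_neighbors(t) + _rerootings(t)
    if moves == "spr":
        nbrs += _spr_neighbors(t)
    cur = canonical(t)
    uniq = {}
    for n in nbrs:
        c = canonical(n)
        if c != cur:
            uniq.setdefault(_ser(c), c)
    return [uniq[k] for k in sorted(uniq)]


def hill_climb(gene_trees: Sequence[UnrootedGeneTree],
               species_set: Iterable[str],
               config: SearchConfig = SearchConfig()) -> SearchResult:
    """Randomized-restart hill climb for the (omega-)kNNIST problem.

    Every run starts from a seeded random rooted topology on ``species_set``
    and strictly descends (ties in the neighbor ranking broken by canonical
    order) until locally optimal.  All distinct final trees are ranked by
    cost; co-optimal finals are all reported.
    """
    species = sorted(set(species_set))
    if len(species) < 2:
        raise TreeError("species set must contain at least 2 species")
    for idx, g in enumerate(gene_trees):
        missing = set(g.leaf_label.values()) - set(species)
        if missing:
            raise TreeError(f"gene tree #{idx} has labels outside the "
                            f"species set: {sorted(missing)}")

    cc = config.correction
    if cc.omega is not None and cc.mu is not None:
        accepted, rejected = filter_by_mu(gene_trees, cc.omega, cc.mu)
    else:
        accepted, rejected = list(gene_trees), []

    memo: dict[str, float] = {}
    stats = {"evals": 0}

    def evaluate(t) -> float:
        key = _ser(t)
        if key not in memo:
            s = SpeciesTree.from_nested(t)
            memo[key] = sum(corrected_cost_value(g, s, cc) for g in accepted)
            stats["evals"] += 1
        return memo[key]

    rng = random.Random(config.seed)
    finals: dict[str, tuple[float, object]] = {}
    trajectories = []

    for _ in range(config.runs):
        t = canonical(random_rooted_topology(species, rng))
        cost = evaluate(t)
        traj = [(t, cost)]
        for _step in range(config.max_steps):
            best_n, best_c = None, cost
            for n in _neighbor_set(t, config.moves):
                c = evaluate(n)
                if c < best_c:
                    best_n, best_c = n, c
            if best_n is None:
                break
            t, cost = best_n, best_c
            traj.append((t, cost))
        finals[_ser(t)] = (cost, t)
        trajectories.append(traj)

    ranking = sorted(((c, t) for c, t in finals.values()),
                     key=lambda ct: (ct[0], _ser(ct[1])))
    best_cost = ranking[0][0]
    best_trees = [t for c, t in ranking if c == best_cost]
    return SearchResult(best_cost=best_cost, best_trees=best_trees,
                        ranking=ranking, trajectories=trajectories,
                        n_accepted=len(accepted), n_rejected=len(rejected),
                        evaluations=stats["evals"])


def total_cost_of_tree(candidate, gene_trees: Sequence[UnrootedGeneTree],
                       config: CorrectionConfig = CorrectionConfig()) -> float:
    """Total corrected cost of one candidate species tree over the gene-tree
    set (after mu-filtering when configured)."""
    if not isinstance(candidate, SpeciesTree):
        candidate = SpeciesTree.from_nested(candidate)
    if config.omega is not None and config.mu is not None:
        gene_trees, _ = filter_by_mu(gene_trees, config.omega, config.mu)
    if not gene_trees:
        return 0.0
    return knnic_total(gene_trees, candidate, config).total
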