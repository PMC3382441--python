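"""NNI rearrangements with constant-time reconciliation-state maintenance.

A nearest-neighbor interchange acts on an internal *center* edge e0 = {x, y}
of an unrooted gene tree viewed as ((T1, T2), (T3, T4)) -- T1, T2 hanging off
x through side edges e1, e2 and T3, T4 off y through e3, e4 -- and exchanges
T1 with T3, giving ((T2, T3), (T1, T4)).  The second interchange per edge is
obtained by renaming the two subtrees at x.  Three facts make the bookkeeping
constant-time:

* only the two arc labels of the center edge change (two lca queries);
* the optimal-edge set Min_G changes only in the five-edge neighborhood
  C_G = {e0, ..., e4}, by a nine-way case analysis (EQ1-EQ4 leave it fixed,
  NE1-NE5 edit it locally);
* the optimal cost moves by a closed-form difference: Delta4 of the four
  side labels when the center rooting survives, else an index-dependent
  Delta3 evaluated at the side labels of the subtree holding a surviving
  optimal edge.

Side edges keep their identity through the rewiring (e_i and its transform
share the Edge object), so lengths and eligibility flags follow the edge.
A safety fallback recomputes everything from scratch if the case analysis
ever fails an internal assertion; fallbacks are counted on the state and are
required to be absent on randomized-walk validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

from .rooted import CostWeights
from .trees import Edge, UnrootedGeneTree
from .unrooted import ReconciliationState, edge_is_symmetric

__all__ = ["NniFrame", "NniDelta", "NniUndo", "enumerate_nni", "make_frame",
           "apply_nni", "undo_nni", "apply_nni_raw", "undo_nni_raw",
           "classify_nni", "delta3", "delta4"]


@dataclass(frozen=True)
class NniFrame:
    """One NNI move: center edge e0 = {x, y}; subtree roots w1, w2 (at x) and
    w3, w4 (at y) reached through side edges e1..e4; the move swaps T1 and T3.
    ``variant`` records which of the two interchanges of the center edge this
    is (0 or 1: which subtree at x plays T1)."""

    e0: Edge
    x: int
    y: int
    w: tuple[int, int, int, int]
    e: tuple[Edge, Edge, Edge, Edge]
    variant: int

    def describe(self) -> tuple[int, int]:
        """(edge id, variant): enough to replay the move deterministically."""
        return (self.e0.id, self.variant)


@dataclass
class NniDelta:
    """Outcome of the case analysis for one move: the lemma case tag, the
    cost difference, and the replacement optimal-edge set (None = fallback
    recomputation required)."""

    case: str
    delta: Optional[float]
    new_minset: Optional[set[Edge]]


@dataclass
class NniUndo:
    frame: NniFrame
    saved_labels: dict
    removed_keys: list
    saved_minset: set[Edge]
    saved_sigma: float


_MISSING = object()


def make_frame(g: UnrootedGeneTree, e0: Edge, variant: int) -> NniFrame:
    """Build the frame for one of the two interchanges of an internal edge.

    Side edges are ordered by edge id, so frames are deterministic for a
    given tree state and ``(edge id, variant)`` replays a move exactly.
    """
    x, y = e0.u, e0.v
    side_x = sorted((e for e in g.adj[x] if e is not e0), key=lambda e: e.id)
    side_y = sorted((e for e in g.adj[y] if e is not e0), key=lambda e: e.id)
    if len(side_x) != 2 or len(side_y) != 2:
        raise ValueError("NNI center must be an internal edge")
    e1, e2 = (side_x[0], side_x[1]) if variant == 0 else (side_x[1], side_x[0])
    e3, e4 = side_y
    return NniFrame(e0=e0, x=x, y=y,
                    w=(e1.other(x), e2.other(x), e3.other(y), e4.other(y)),
                    e=(e1, e2, e3, e4), variant=variant)


def enumerate_nni(g: UnrootedGeneTree,
                  allowed_edges: Optional[Sequence[Edge]] = None) -> Iterator[NniFrame]:
    """Both NNI variants for every internal edge (or the given subset)."""
    edges = g.internal_edges() if allowed_edges is None else [
        e for e in sorted(allowed_edges, key=lambda e: e.id)
        if not g.is_leaf(e.u) and not g.is_leaf(e.v)]
    for e0 in edges:
        for variant in (0, 1):
            yield make_frame(g, e0, variant)


# ---------------------------------------------------------------------------
# Raw topology rewiring (no reconciliation state)
# ---------------------------------------------------------------------------

def apply_nni_raw(g: UnrootedGeneTree, frame: NniFrame) -> None:
    """Rewire the tree per the frame (swap T1 and T3); labels untouched."""
    x, y = frame.x, frame.y
    e1, e3 = frame.e[0], frame.e[2]
    if not (x in frame.e0.nodes() and y in frame.e0.nodes()
            and x in e1.nodes() and y in e3.nodes()):
        raise ValueError("stale NNI frame: tree changed since enumeration")
    g.adj[x][g.adj[x].index(e1)] = e3
    g.adj[y][g.adj[y].index(e3)] = e1
    e1.replace_endpoint(x, y)
    e3.replace_endpoint(y, x)


def undo_nni_raw(g: UnrootedGeneTree, frame: NniFrame) -> None:
    x, y = frame.x, frame.y
    e1, e3 = frame.e[0], frame.e[2]
    g.adj[y][g.adj[y].index(e1)] = e3
    g.adj[x][g.adj[x].index(e3)] = e1
    e1.replace_endpoint(y, x)
    e3.replace_endpoint(x, y)


# ---------------------------------------------------------------------------
# Closed-form cost differences
# ---------------------------------------------------------------------------

def _phi(s, a: int, b: int, c: int, w: CostWeights) -> float:
    """Contribution of a rooted ((x, y), z) fragment whose nodes map to
    a, b, c: duplications/losses of the node xy and of its parent."""
    ab = s.lca(a, b)
    return (w.alpha * (s.comparable(a, b) + s.comparable(ab, c))
            + w.beta * (s.loss_count(a, b) + s.loss_count(ab, c)))


def delta3(s, a: int, b: int, c: int, w: CostWeights = CostWeights()) -> float:
    """Cost difference of rearranging ((x, y), z) into (x, (y, z)) when the
    three subtrees map to a, b, c: phi(c, b, a) - phi(a, b, c)."""
    return _phi(s, c, b, a, w) - _phi(s, a, b, c, w)


def _phi4(s, a: int, b: int, c: int, d: int, w: CostWeights) -> float:
    """Contribution of ((x, y), (z, v)) mapped to a, b, c, d."""
    return (_phi(s, a, b, s.lca(c, d), w)
            + w.alpha * s.comparable(c, d) + w.beta * s.loss_count(c, d))


def delta4(s, a: int, b: int, c: int, d: int,
           w: CostWeights = CostWeights()) -> float:
    """Cost difference of rearranging ((x, y), (z, v)) into ((x, v), (y, z))
    at the center rooting: phi'(a, d, b, c) - phi'(a, b, c, d)."""
    return _phi4(s, a, d, b, c, w) - _phi4(s, a, b, c, d, w)


# Delta3 argument order per surviving subtree index (swap T1 <-> T3 frame):
# i = 1 -> (a4, a3, a2); 2 -> (a3, a4, a1); 3 -> (a2, a1, a4); 4 -> (a1, a2, a3)
_DELTA3_ARGS = {1: (3, 2, 1), 2: (2, 3, 0), 3: (1, 0, 3), 4: (0, 1, 2)}


# ---------------------------------------------------------------------------
# Case analysis (Min_G and cost update)
# ---------------------------------------------------------------------------

def classify_nni(state: ReconciliationState, frame: NniFrame) -> NniDelta:
    """Decide the lemma case for a move and compute the new Min_G and the
    cost difference, without touching the state.

    Case tags: EQ1-EQ4 leave Min_G unchanged; NE1-NE5 edit it inside the
    five-edge neighborhood.  A non-classifiable configuration returns the
    FALLBACK tag (full recomputation; counted by the caller).
    """
    s, labels, top, w = state.s, state.labels, state.top, state.weights
    x, y = frame.x, frame.y
    e0 = frame.e0
    e = frame.e
    a = (labels[(frame.w[0], x)], labels[(frame.w[1], x)],
         labels[(frame.w[2], y)], labels[(frame.w[3], y)])
    C = [e0, *e]
    inter = [ed for ed in C if ed in state.minset]

    new_xy = s.lca(a[1], a[2])   # x retains T2, gains T3
    new_yx = s.lca(a[0], a[3])   # y retains T4, gains T1
    new_center_symmetric = ((new_xy == top) + (new_yx == top)) != 1

    def d3(i: int) -> float:
        p, q, r = _DELTA3_ARGS[i]
        return delta3(s, a[p], a[q], a[r], w)

    def d4() -> float:
        return delta4(s, a[0], a[1], a[2], a[3], w)

    def side_asym(i: int) -> bool:
        return not edge_is_symmetric(labels, e[i - 1], top)

    # post-NNI stars through the center: at x: {e0, e2, e3}; at y: {e0, e1, e4}
    post_star_mate = {1: e[3], 4: e[0], 2: e[2], 3: e[1]}

    if not inter:
        # EQ1: optimal edges untouched; locate the subtree holding Min_G by
        # following the direction of the non-top arc labels.
        cands = []
        for i in (1, 2, 3, 4):
            c_node = x if i <= 2 else y
            w_node = frame.w[i - 1]
            if labels[(c_node, w_node)] != top and labels[(w_node, c_node)] == top:
                cands.append(i)
        if len(cands) != 1:
            return NniDelta("FALLBACK", None, None)
        return NniDelta("EQ1", d3(cands[0]), set(state.minset))

    if inter == [e0] and len(state.minset) == 1:
        # EQ3: the single optimal edge is the (symmetric) center; it stays.
        return NniDelta("EQ3", d4(), set(state.minset))

    if len(inter) == 5:
        # Min_G covers the whole neighborhood: two S4/S5 stars.
        pair = None
        for i, j in ((1, 4), (2, 3)):  # semi-alternating pairs after the swap
            if side_asym(i) and side_asym(j):
                pair = (i, j)
                break
        if pair is None:
            return NniDelta("EQ2", d4(), set(state.minset))
        new_min = set(state.minset) - {e[pair[0] - 1], e[pair[1] - 1]}
        return NniDelta("NE1", d4(), new_min)

    if len(inter) == 1 and inter[0] is not e0:
        i = next(i for i in (1, 2, 3, 4) if e[i - 1] is inter[0])
        if not new_center_symmetric:
            return NniDelta("EQ4", d3(i), set(state.minset))
        new_min = set(state.minset) | {e0, post_star_mate[i]}
        return NniDelta("NE2", d3(i), new_min)

    if len(inter) == 3 and e0 in inter:
        others = [i for i in (1, 2, 3, 4) if e[i - 1] in inter]
        if others not in ([1, 2], [3, 4]):
            return NniDelta("FALLBACK", None, None)  # not a star in G
        i, j = others
        si, sj = not side_asym(i), not side_asym(j)
        if si and sj:
            return NniDelta("NE3", d4(), set(state.minset) | set(e))
        if si != sj:
            if not si:
                i, j = j, i  # i symmetric, j asymmetric
            base = set(state.minset) - set(C)
            if new_center_symmetric:
                # NE4: the center edge is optimal before and after, so the
                # Delta4 form applies here as well.
                star = {e0, e[i - 1], post_star_mate[i]}
                return NniDelta("NE4", d4(), base | star)
            return NniDelta("NE5", d3(i), base | {e[i - 1]})
        return NniDelta("FALLBACK", None, None)  # two asymmetric edges in one star

    return NniDelta("FALLBACK", None, None)


# ---------------------------------------------------------------------------
# Stateful apply / undo
# ---------------------------------------------------------------------------

def apply_nni(state: ReconciliationState, frame: NniFrame) -> NniUndo:
    """Apply the move, maintaining labels (Lemma-1 locality: only the two
    center arcs are recomputed), Min_G and sigma incrementally; returns an
    undo token restoring the exact prior state."""
    g, s, labels = state.g, state.s, state.labels
    x, y = frame.x, frame.y
    w1, w3 = frame.w[0], frame.w[2]

    decision = classify_nni(state, frame)
    state.case_counts[decision.case] += 1

    saved_minset = state.minset
    saved_sigma = state.sigma

    a1 = labels[(w1, x)]
    a3 = labels[(w3, y)]
    touched = [(w1, x), (x, w1), (w3, y), (y, w3), (x, y), (y, x),
               (w1, y), (y, w1), (w3, x), (x, w3)]
    saved_labels = {k: labels.get(k, _MISSING) for k in touched}

    apply_nni_raw(g, frame)

    comp1 = labels.pop((x, w1))   # complement label of T1 (unchanged value)
    comp3 = labels.pop((y, w3))
    del labels[(w1, x)]
    del labels[(w3, y)]
    labels[(w1, y)] = a1
    labels[(y, w1)] = comp1
    labels[(w3, x)] = a3
    labels[(x, w3)] = comp3
    labels[(x, y)] = s.lca(labels[(frame.w[1], x)], a3)
    labels[(y, x)] = s.lca(a1, labels[(frame.w[3], y)])

    if decision.case == "FALLBACK":
        state.fallback_count += 1
        state.recompute()
    else:
        state.minset = decision.new_minset
        state.sigma = saved_sigma + decision.delta

    return NniUndo(frame=frame, saved_labels=saved_labels,
                   removed_keys=[(w1, y), (y, w1), (w3, x), (x, w3)],
                   saved_minset=saved_minset, saved_sigma=saved_sigma)


def undo_nni(state: ReconciliationState, token: NniUndo) -> None:
    """Restore topology, labels, Min_G and sigma exactly as before the move."""
    undo_nni_raw(state.g, token.frame)
    labels = state.labels
    for k in token.removed_keys:
        labels.pop(k, None)
    for k, v in token.saved_labels.items():
        if v is _MISSING:
            labels.pop(k, None)
        else:
            labels[k] = v
    state.minset = token.saved_minset
    state.sigma = token.saved_sigma
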