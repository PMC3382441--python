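"""Tree containers and species-tree order/metric primitives.

Two in-memory containers back everything else:

* :class:`SpeciesTree` -- a rooted binary tree over a species set, viewed as an
  upper semilattice: ``lca(a, b)`` is the least upper bound of two nodes, the
  root is the top element.  Constant-time lca queries are served by an Euler
  tour + sparse-table index.  The tree also answers the comparability
  predicate ``D``, the path-length metric ``rho``, the sibling set ``Sb`` and
  the loss count ``L`` used by duplication-loss reconciliation.
* :class:`UnrootedGeneTree` -- an undirected tree whose nodes have degree 3
  (internal) or 1 (leaves), leaves labeled by species identifiers (duplicate
  labels allowed), with optional non-negative edge lengths.  Edges are objects
  with persistent identity so that NNI rearrangements can rewire endpoints
  while lengths and eligibility flags follow the edge.

Newick parsing is delegated to dendropy; serialization is a small
deterministic emitter (unrooted trees are written with a trifurcation anchored
at a canonical internal node).
"""

from __future__ import annotations

from typing import Iterable, Optional, Union

import dendropy

__all__ = [
    "SpeciesTree",
    "LcaIndex",
    "Edge",
    "UnrootedGeneTree",
    "RootedGeneTree",
    "parse_newick",
    "write_newick",
    "TreeError",
]


class TreeError(ValueError):
    """Malformed or unsupported tree input."""


def _format_length(x: float) -> str:
    return f"{x:.10g}"


def _dendropy_tree(text: str) -> dendropy.Tree:
    try:
        # taxa suppressed so that duplicate leaf labels (paralogs) parse;
        # labels are read back from node.label
        return dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise TreeError(f"malformed newick: {exc}") from exc


def _leaf_label(node) -> str:
    lab = node.label if node.label else (node.taxon.label if node.taxon else None)
    if not lab:
        raise TreeError("unlabeled gene leaf")
    return lab


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

class SpeciesTree:
    """Rooted binary species tree with constant-time lca queries.

    Nodes are small integers.  Leaves carry unique species labels; every
    internal node has exactly two children.  ``cluster[v]`` is a bitmask of
    the leaf labels below ``v`` (bit positions follow ``self.labels``, the
    sorted label list), which makes the ancestor test a subset test.
    """

    def __init__(self, parent: list[Optional[int]], children: list[tuple[int, ...]],
                 leaf_label: dict[int, str]):
        self.parent = parent
        self.children = children
        self.leaf_label = dict(leaf_label)
        self.n_nodes = len(parent)
        roots = [v for v in range(self.n_nodes) if parent[v] is None]
        if len(roots) != 1:
            raise TreeError("species tree must have exactly one root")
        self.root = roots[0]
        for v in range(self.n_nodes):
            if len(children[v]) not in (0, 2):
                raise TreeError("species tree must be binary")
            if len(children[v]) == 0 and v not in self.leaf_label:
                raise TreeError("unlabeled species leaf")
        labels = sorted(self.leaf_label.values())
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate species labels")
        if len(labels) < 2:
            raise TreeError("species tree needs at least 2 leaves")
        self.labels: list[str] = labels
        self._bit = {lab: i for i, lab in enumerate(labels)}

        self.depth = [0] * self.n_nodes
        self.cluster = [0] * self.n_nodes
        order = self.preorder()
        for v in order:
            p = self.parent[v]
            self.depth[v] = 0 if p is None else self.depth[p] + 1
        for v in reversed(order):
            if self.children[v]:
                a, b = self.children[v]
                self.cluster[v] = self.cluster[a] | self.cluster[b]
            else:
                self.cluster[v] = 1 << self._bit[self.leaf_label[v]]
        self.label_to_leaf = {self.leaf_label[v]: v for v in self.leaf_label}
        self._index = LcaIndex(self)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        t = _dendropy_tree(text)
        parent: list[Optional[int]] = []
        children: list[list[int]] = []
        leaf_label: dict[int, str] = {}
        ids: dict = {}

        def visit(node, par):
            i = len(parent)
            ids[node] = i
            parent.append(par)
            children.append([])
            if par is not None:
                children[par].append(i)
            if not node.child_nodes():
                leaf_label[i] = _leaf_label(node)
            for ch in node.child_nodes():
                visit(ch, i)

        visit(t.seed_node, None)
        return cls(parent, [tuple(c) for c in children], leaf_label)

    @classmethod
    def from_nested(cls, nested) -> "SpeciesTree":
        """Build from nested tuples: a leaf is a label string, an internal
        node is a pair ``(left, right)``."""
        parent: list[Optional[int]] = []
        children: list[list[int]] = []
        leaf_label: dict[int, str] = {}

        def visit(node, par):
            i = len(parent)
            parent.append(par)
            children.append([])
            if par is not None:
                children[par].append(i)
            if isinstance(node, str):
                leaf_label[i] = node
            else:
                l, r = node
                visit(l, i)
                visit(r, i)

        visit(nested, None)
        return cls(parent, [tuple(c) for c in children], leaf_label)

    # -- basic structure ---------------------------------------------------

    def preorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    def sibling(self, v: int) -> int:
        p = self.parent[v]
        if p is None:
            raise TreeError("root has no sibling")
        a, b = self.children[p]
        return b if a == v else a

    def name(self, v: int) -> str:
        """Human-readable node name: concatenated sorted leaf labels
        (the cluster ``bc``, ``abc`` convention)."""
        labs = sorted(lab for lab in self.labels
                      if self.cluster[v] >> self._bit[lab] & 1)
        sep = "" if all(len(l) == 1 for l in labs) else "+"
        return sep.join(labs)

    def node_of_cluster(self, labels: Iterable[str]) -> int:
        """Node whose cluster is exactly the given label set (KeyError if none)."""
        mask = 0
        for lab in labels:
            mask |= 1 << self._bit[lab]
        for v in range(self.n_nodes):
            if self.cluster[v] == mask:
                return v
        raise KeyError(f"no node with cluster {sorted(labels)}")

    def to_nested(self, v: Optional[int] = None):
        v = self.root if v is None else v
        if self.is_leaf(v):
            return self.leaf_label[v]
        a, b = self.children[v]
        return (self.to_nested(a), self.to_nested(b))

    # -- semilattice / metric primitives ----------------------------------

    def lca(self, a: int, b: int) -> int:
        """Least upper bound ``a + b`` (constant time after preprocessing)."""
        return self._index.lca(a, b)

    def lca_naive(self, a: int, b: int) -> int:
        """Upward-walk lca; reference implementation for tests."""
        seen = set()
        while a is not None:
            seen.add(a)
            a = self.parent[a]
        while b not in seen:
            b = self.parent[b]
        return b

    def leq(self, a: int, b: int) -> bool:
        """``a <= b``: a lies in the subtree of b."""
        return self.cluster[a] | self.cluster[b] == self.cluster[b]

    def comparable(self, a: int, b: int) -> int:
        """Comparability predicate D(a, b): 1 iff a and b lie on one
        root-to-leaf path."""
        return 1 if (self.leq(a, b) or self.leq(b, a)) else 0

    def distance(self, a: int, b: int) -> int:
        """Path length rho(a, b) = depth(a) + depth(b) - 2 depth(a+b)."""
        return self.depth[a] + self.depth[b] - 2 * self.depth[self.lca(a, b)]

    def sibling_set(self, a: int, b: int) -> frozenset[int]:
        """The set Sb(a, b) of lineages branching off the a--b path.

        Three-case recurrence: (i) empty when ``a == b`` or the two nodes are
        siblings; (ii) when ``a < b`` or ``a + c < a + b`` (``c`` the sibling
        of ``a``, so ``a + c`` is a's parent), collect ``c`` and recurse on
        ``(a + c, b)``; (iii) otherwise swap the arguments.
        """
        if a == b:
            return frozenset()
        pa, pb = self.parent[a], self.parent[b]
        if pa is not None and pa == pb:
            return frozenset()
        if pa is not None:
            ab = self.lca(a, b)
            if (self.leq(a, b) and a != b) or (self.leq(pa, ab) and pa != ab):
                return frozenset({self.sibling(a)}) | self.sibling_set(pa, b)
        return self.sibling_set(b, a)

    def loss_count(self, a: int, b: int) -> int:
        """L(a, b) = rho(a, b) - 2 (1 - D(a, b)), the number of lineages in
        Sb(a, b) (gene losses charged to a node mapping pair)."""
        return self.distance(a, b) - 2 * (1 - self.comparable(a, b))

    def lca_of_labels(self, labels: Iterable[str]) -> int:
        it = iter(labels)
        try:
            v = self.label_to_leaf[next(it)]
        except StopIteration:
            raise TreeError("empty label set")
        except KeyError as exc:
            raise TreeError(f"unknown species label {exc}") from exc
        for lab in it:
            try:
                v = self.lca(v, self.label_to_leaf[lab])
            except KeyError as exc:
                raise TreeError(f"unknown species label {exc}") from exc
        return v

    # -- output ------------------------------------------------------------

    def newick(self) -> str:
        def rec(v):
            if self.is_leaf(v):
                return self.leaf_label[v]
            a, b = self.children[v]
            return f"({rec(a)},{rec(b)})"
        return rec(self.root) + ";"

    def __repr__(self) -> str:
        return f"SpeciesTree({self.newick()!r})"


class LcaIndex:
    """Euler tour + sparse table: O(|S| log |S|) build, O(1) lca queries."""

    def __init__(self, tree: SpeciesTree):
        tour: list[int] = []
        first: dict[int, int] = {}
        depth = tree.depth

        # iterative Euler tour
        path: list[int] = []
        v = tree.root
        idx = [0] * tree.n_nodes
        path.append(v)
        while path:
            v = path[-1]
            if v not in first:
                first[v] = len(tour)
            tour.append(v)
            if idx[v] < len(tree.children[v]):
                c = tree.children[v][idx[v]]
                idx[v] += 1
                path.append(c)
            else:
                path.pop()
        self.first = first
        m = len(tour)
        levels = [[(depth[v], v) for v in tour]]
        k = 1
        while (1 << k) <= m:
            prev = levels[-1]
            half = 1 << (k - 1)
            levels.append([min(prev[i], prev[i + half])
                           for i in range(m - (1 << k) + 1)])
            k += 1
        self.levels = levels

    def lca(self, a: int, b: int) -> int:
        i, j = self.first[a], self.first[b]
        if i > j:
            i, j = j, i
        span = j - i + 1
        k = span.bit_length() - 1
        lvl = self.levels[k]
        return min(lvl[i], lvl[j - (1 << k) + 1])[1]


# ---------------------------------------------------------------------------
# Unrooted gene tree
# ---------------------------------------------------------------------------

class Edge:
    """Undirected edge with persistent identity across NNI rewiring."""

    __slots__ = ("id", "u", "v", "length")

    def __init__(self, eid: int, u: int, v: int, length: Optional[float] = None):
        self.id = eid
        self.u = u
        self.v = v
        self.length = length

    def other(self, node: int) -> int:
        if node == self.u:
            return self.v
        if node == self.v:
            return self.u
        raise ValueError("node not on edge")

    def nodes(self) -> tuple[int, int]:
        return (self.u, self.v)

    def replace_endpoint(self, old: int, new: int) -> None:
        if self.u == old:
            self.u = new
        elif self.v == old:
            self.v = new
        else:
            raise ValueError("endpoint not on edge")

    def __repr__(self) -> str:
        return f"Edge({self.id}, {self.u}-{self.v}, len={self.length})"


class UnrootedGeneTree:
    """Unrooted gene tree: degree-3 internal nodes, species-labeled leaves.

    ``adj[v]`` lists the incident :class:`Edge` objects of node ``v``.
    Duplicate leaf labels are allowed (paralogs).
    """

    def __init__(self):
        self.adj: dict[int, list[Edge]] = {}
        self.leaf_label: dict[int, str] = {}
        self.edges: list[Edge] = []
        self._next_node = 0

    # -- construction -----------------------------------------------------

    def _new_node(self, label: Optional[str] = None) -> int:
        v = self._next_node
        self._next_node += 1
        self.adj[v] = []
        if label is not None:
            self.leaf_label[v] = label
        return v

    def _add_edge(self, u: int, v: int, length: Optional[float]) -> Edge:
        e = Edge(len(self.edges), u, v, length)
        self.edges.append(e)
        self.adj[u].append(e)
        self.adj[v].append(e)
        return e

    @classmethod
    def from_newick(cls, text: str) -> "UnrootedGeneTree":
        t = _dendropy_tree(text)
        g = cls()
        ids: dict = {}

        def visit(node, par):
            if not node.child_nodes():
                i = g._new_node(_leaf_label(node))
            else:
                i = g._new_node()
            ids[node] = i
            if par is not None:
                g._add_edge(ids[par], i, node.edge.length)
            for ch in node.child_nodes():
                visit(ch, node)

        visit(t.seed_node, None)
        g._suppress_degree2()
        g._validate()
        return g

    @classmethod
    def from_nested(cls, nested, lengths: bool = False) -> "UnrootedGeneTree":
        """Build from nested tuples (rooted form; the root is suppressed).

        A leaf may be a label string or ``(label, length)``; an internal node
        a pair of subtrees.
        """
        g = cls()

        def visit(node, par):
            if isinstance(node, str):
                i = g._new_node(node)
                ln = None
            elif lengths and len(node) == 2 and isinstance(node[0], str) \
                    and isinstance(node[1], (int, float)):
                i = g._new_node(node[0])
                ln = float(node[1])
            else:
                i = g._new_node()
                ln = None
                for ch in node:
                    visit(ch, i)
            if par is not None:
                g._add_edge(par, i, ln)

        visit(nested, None)
        g._suppress_degree2()
        g._validate()
        return g

    def _suppress_degree2(self) -> None:
        # a parsed rooted-binary newick leaves a degree-2 root; merge its two
        # incident edges additively (None-aware)
        changed = True
        while changed:
            changed = False
            for v in list(self.adj):
                if len(self.adj[v]) == 2 and v not in self.leaf_label:
                    e1, e2 = self.adj[v]
                    a, b = e1.other(v), e2.other(v)
                    if e1.length is None and e2.length is None:
                        ln = None
                    else:
                        ln = (e1.length or 0.0) + (e2.length or 0.0)
                    self.adj[a].remove(e1)
                    self.adj[b].remove(e2)
                    del self.adj[v]
                    self.edges.remove(e1)
                    self.edges.remove(e2)
                    e = self._add_edge(a, b, ln)
                    changed = True
                    break
        # renumber edge ids densely, keeping order
        for i, e in enumerate(self.edges):
            e.id = i

    def _validate(self) -> None:
        for v, inc in self.adj.items():
            d = len(inc)
            if v in self.leaf_label:
                if d != 1:
                    raise TreeError("labeled leaf with degree != 1")
            elif d != 3:
                raise TreeError(f"internal node with degree {d} (binary trees only)")
        if len(self.leaf_label) < 2:
            raise TreeError("gene tree needs at least 2 leaves")

    # -- structure ---------------------------------------------------------

    @property
    def nodes(self) -> list[int]:
        return sorted(self.adj)

    def is_leaf(self, v: int) -> bool:
        return v in self.leaf_label

    def n_leaves(self) -> int:
        return len(self.leaf_label)

    def labels(self) -> list[str]:
        return sorted(self.leaf_label.values())

    def internal_edges(self) -> list[Edge]:
        return [e for e in self.edges
                if not self.is_leaf(e.u) and not self.is_leaf(e.v)]

    def neighbors(self, v: int) -> list[tuple[int, Edge]]:
        return [(e.other(v), e) for e in self.adj[v]]

    def copy(self) -> "UnrootedGeneTree":
        g = UnrootedGeneTree()
        g._next_node = self._next_node
        g.leaf_label = dict(self.leaf_label)
        g.adj = {v: [] for v in self.adj}
        for e in self.edges:
            ne = Edge(e.id, e.u, e.v, e.length)
            g.edges.append(ne)
            g.adj[ne.u].append(ne)
            g.adj[ne.v].append(ne)
        return g

    def side_leaves(self, edge: Edge, endpoint: int) -> list[str]:
        """Leaf labels in the component of ``endpoint`` after removing ``edge``."""
        out, stack, seen = [], [(endpoint, edge)], set()
        while stack:
            v, came = stack.pop()
            seen.add(v)
            if self.is_leaf(v):
                out.append(self.leaf_label[v])
            for e in self.adj[v]:
                if e is came:
                    continue
                w = e.other(v)
                if w not in seen:
                    stack.append((w, e))
        return sorted(out)

    def bipartition(self, edge: Edge) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """Canonical leaf-label bipartition induced by an edge."""
        a = tuple(self.side_leaves(edge, edge.u))
        b = tuple(self.side_leaves(edge, edge.v))
        return (a, b) if a <= b else (b, a)

    def topology_key(self) -> tuple:
        """Canonical encoding of the unrooted topology (leaf multiset plus the
        sorted internal-edge bipartitions); equal keys iff label-isomorphic."""
        bips = sorted(self.bipartition(e) for e in self.internal_edges())
        return (tuple(self.labels()), tuple(bips))

    # -- output ------------------------------------------------------------

    def newick(self, with_lengths: bool = True) -> str:
        """Newick with a top-level trifurcation at a canonical internal node
        (the internal node adjacent to the lexicographically smallest leaf);
        a 2-leaf tree is written as a cherry."""
        if len(self.adj) == 2:
            (a, b) = sorted(self.adj)
            e = self.edges[0]
            sa, sb = self.leaf_label[a], self.leaf_label[b]
            if with_lengths and e.length is not None:
                return f"({sa}:{_format_length(e.length)},{sb}:0);"
            return f"({sa},{sb});"

        min_leaf = min(self.leaf_label, key=lambda v: (self.leaf_label[v], v))
        anchor = self.adj[min_leaf][0].other(min_leaf)

        def rec(v, came: Edge) -> str:
            if self.is_leaf(v):
                s = self.leaf_label[v]
            else:
                parts = [rec(e.other(v), e) for e in self.adj[v] if e is not came]
                s = "(" + ",".join(parts) + ")"
            if with_lengths and came is not None and came.length is not None:
                s += ":" + _format_length(came.length)
            return s

        parts = [rec(e.other(anchor), e) for e in self.adj[anchor]]
        return "(" + ",".join(parts) + ");"

    def __repr__(self) -> str:
        return f"UnrootedGeneTree({self.newick(with_lengths=False)!r})"


# ---------------------------------------------------------------------------
# Rooted gene tree
# ---------------------------------------------------------------------------

class RootedGeneTree:
    """Rooted binary gene tree (species-labeled leaves, duplicates allowed)."""

    def __init__(self, children: list[tuple[int, ...]], leaf_label: dict[int, str],
                 root: int, source_edge: Optional[Edge] = None):
        self.children = children
        self.leaf_label = dict(leaf_label)
        self.root = root
        self.n_nodes = len(children)
        #: the unrooted edge this rooting subdivided, when applicable
        self.source_edge = source_edge

    @classmethod
    def from_newick(cls, text: str) -> "RootedGeneTree":
        t = _dendropy_tree(text)
        children: list[list[int]] = []
        leaf_label: dict[int, str] = {}

        def visit(node):
            i = len(children)
            children.append([])
            if not node.child_nodes():
                leaf_label[i] = _leaf_label(node)
            for ch in node.child_nodes():
                children[i].append(visit(ch))
            return i

        root = visit(t.seed_node)
        for c in children:
            if len(c) not in (0, 2):
                raise TreeError("rooted gene tree must be binary")
        return cls([tuple(c) for c in children], leaf_label, root)

    @classmethod
    def from_nested(cls, nested) -> "RootedGeneTree":
        """Build from nested tuples (leaf = label string, internal = pair)."""
        children: list[list[int]] = []
        leaf_label: dict[int, str] = {}

        def visit(node):
            i = len(children)
            children.append([])
            if isinstance(node, str):
                leaf_label[i] = node
            else:
                for ch in node:
                    children[i].append(visit(ch))
            return i

        visit(nested)
        for c in children:
            if len(c) not in (0, 2):
                raise TreeError("rooted gene tree must be binary")
        return cls([tuple(c) for c in children], leaf_label, 0)

    @classmethod
    def from_rooting(cls, g: UnrootedGeneTree, edge: Edge) -> "RootedGeneTree":
        """Rooting G_e: subdivide ``edge`` with a new root node v_*."""
        children: list[list[int]] = [[]]  # node 0 is the new root v_*
        leaf_label: dict[int, str] = {}

        def visit(v: int, came: Edge) -> int:
            i = len(children)
            children.append([])
            if g.is_leaf(v):
                leaf_label[i] = g.leaf_label[v]
            else:
                for e in g.adj[v]:
                    if e is came:
                        continue
                    children[i].append(visit(e.other(v), e))
            return i

        a = visit(edge.u, edge)
        b = visit(edge.v, edge)
        children[0] = [a, b]
        return cls([tuple(c) for c in children], leaf_label, 0, source_edge=edge)

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    def postorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    def internal_nodes(self) -> list[int]:
        return [v for v in range(self.n_nodes) if self.children[v]]

    def labels(self) -> list[str]:
        return sorted(self.leaf_label.values())

    def newick(self) -> str:
        def rec(v):
            if self.is_leaf(v):
                return self.leaf_label[v]
            a, b = self.children[v]
            return f"({rec(a)},{rec(b)})"
        return rec(self.root) + ";"

    def to_nested(self, v: Optional[int] = None):
        v = self.root if v is None else v
        if self.is_leaf(v):
            return self.leaf_label[v]
        a, b = self.children[v]
        return (self.to_nested(a), self.to_nested(b))

    def __repr__(self) -> str:
        return f"RootedGeneTree({self.newick()!r})"


# ---------------------------------------------------------------------------
# Front door
# ---------------------------------------------------------------------------

def parse_newick(text: str, kind: str = "gene"):
    """Parse a newick string as a ``species`` or ``gene`` tree.

    Species trees must be rooted, binary and uniquely labeled.  Gene trees may
    be rooted-binary or top-level trifurcating; a degree-2 root is suppressed
    (root-adjacent lengths merge additively) to give the unrooted form.
    """
    if kind == "species":
        return SpeciesTree.from_newick(text)
    if kind == "gene":
        return UnrootedGeneTree.from_newick(text)
    if kind == "rooted_gene":
        return RootedGeneTree.from_newick(text)
    raise ValueError(f"unknown tree kind {kind!r}")


def write_newick(tree: Union[SpeciesTree, UnrootedGeneTree, RootedGeneTree]) -> str:
    return tree.newick()
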