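"""Unrooted phylogenetic trees and forests with edge lengths in [0, inf].

The central object is :class:`Forest`: a disjoint union of unrooted trees
whose leaves are bijectively labelled ``1..N`` and whose edges carry a
length ``l >= 0`` (possibly infinite) or, equivalently, a weight
``lam = 1 - exp(-l)`` in ``[0, 1]``.  Forests are points of *wald space*
once two equivalence rules are imposed:

* **BHV boundary rule** -- an internal edge of weight 0 may be contracted
  (its endpoints merged) without changing the induced character
  distribution.
* **Boundary-at-infinity rule** -- an edge of weight 1 may be deleted,
  disconnecting its tree; any unlabelled degree-2 vertex this creates is
  suppressed, the two incident edges being merged into one whose length is
  the sum of the two (weights combine as ``a + b - a*b``).

:func:`canonicalize` applies both rules exhaustively, yielding the unique
reduced representative of an equivalence class, and
:func:`forests_equivalent` compares canonical forms.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Forest",
    "Split",
    "Topology",
    "parse_newick",
    "write_newick",
    "leaf_distance_matrix",
    "split_matrix",
    "canonicalize",
    "forests_equivalent",
    "enumerate_topologies",
    "nni_neighbors",
    "length_to_weight",
    "weight_to_length",
    "length_weight_convert",
    "tree_from_splits",
]

#: absolute tolerance used when comparing edge lengths of canonical forests
LENGTH_TOL = 1e-12

#: guard for the double-factorial topology enumeration
MAX_ENUM_LEAVES = 9


# ---------------------------------------------------------------------------
# length <-> weight
# ---------------------------------------------------------------------------

def length_to_weight(length: float) -> float:
    """Map an edge length ``l in [0, inf]`` to its weight ``1 - exp(-l)``."""
    if length < 0:
        raise ValueError(f"edge length must be >= 0, got {length}")
    return -math.expm1(-length)


def weight_to_length(weight: float) -> float:
    """Inverse map: weight ``lam in [0, 1]`` to length ``-log(1 - lam)``."""
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"edge weight must be in [0, 1], got {weight}")
    if weight == 1.0:
        return math.inf
    return -math.log1p(-weight)


def length_weight_convert(x: float, direction: str) -> float:
    """Convert between length and weight parametrizations.

    ``direction`` is ``"to_weight"`` or ``"to_length"``.
    """
    if direction == "to_weight":
        return length_to_weight(x)
    if direction == "to_length":
        return weight_to_length(x)
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# splits and topologies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Split:
    """A bipartition of (a subset of) the leaf labels.

    ``side1`` is always the canonical side: the smaller of the two sides,
    ties broken by sorted-tuple order, so equal bipartitions compare equal.
    """

    side1: frozenset[int]
    side2: frozenset[int]

    @staticmethod
    def of(a: Iterable[int], b: Iterable[int]) -> "Split":
        fa, fb = frozenset(a), frozenset(b)
        if not fa or not fb:
            raise ValueError("both sides of a split must be non-empty")
        if fa & fb:
            raise ValueError("split sides must be disjoint")
        ka, kb = (len(fa), tuple(sorted(fa))), (len(fb), tuple(sorted(fb)))
        return Split(fa, fb) if ka <= kb else Split(fb, fa)

    @property
    def is_pendant(self) -> bool:
        return len(self.side1) == 1

    @property
    def all_leaves(self) -> frozenset[int]:
        return self.side1 | self.side2

    def key(self) -> tuple:
        return (len(self.side1), tuple(sorted(self.side1)),
                tuple(sorted(self.side2)))

    def separates(self, u: int, v: int) -> bool:
        return (u in self.side1) != (v in self.side1)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        a = ",".join(map(str, sorted(self.side1)))
        b = ",".join(map(str, sorted(self.side2)))
        return f"{{{a}}}|{{{b}}}"


def splits_compatible(s1: Split, s2: Split) -> bool:
    """Two splits of the same leaf set are compatible iff some pair of
    opposite sides is disjoint."""
    return any(
        not (a & b)
        for a in (s1.side1, s1.side2)
        for b in (s2.side1, s2.side2)
    )


@dataclass(frozen=True)
class Topology:
    """A tree topology: the set of splits displayed by a single tree."""

    splits: frozenset[Split]

    def __post_init__(self) -> None:
        leaves = self.leaves
        for s in self.splits:
            if s.all_leaves != leaves:
                raise ValueError("all splits must partition the same leaf set")

    @property
    def leaves(self) -> frozenset[int]:
        return next(iter(self.splits)).all_leaves

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def internal_splits(self) -> frozenset[Split]:
        return frozenset(s for s in self.splits if not s.is_pendant)

    @property
    def resolved(self) -> bool:
        return len(self.splits) == 2 * self.n_leaves - 3

    def sorted_splits(self) -> list[Split]:
        """Deterministic split ordering: pendant splits by leaf label, then
        internal splits lexicographically by their smaller side."""
        return sorted(self.splits, key=Split.key)

    def sort_key(self) -> tuple:
        return tuple(s.key() for s in self.sorted_splits())

    def to_tree(self, lengths: Mapping[Split, float] | Sequence[float]) -> "Forest":
        """Realize this topology as a Forest with the given edge lengths.

        ``lengths`` is either a mapping ``Split -> length`` or a sequence in
        ``sorted_splits()`` order.
        """
        order = self.sorted_splits()
        if not isinstance(lengths, Mapping):
            if len(lengths) != len(order):
                raise ValueError("length vector does not match split count")
            lengths = dict(zip(order, lengths))
        return tree_from_splits(lengths, n_leaves=max(self.leaves))


def tree_from_splits(lengths: Mapping[Split, float], n_leaves: int | None = None) -> "Forest":
    """Build the unique tree displaying a compatible split system.

    Every leaf must be covered by a pendant split; internal splits are
    inserted by repeatedly pulling apart the vertex whose neighbourhood
    refines the split.
    """
    splits = list(lengths)
    leaves = sorted({x for s in splits for x in s.all_leaves})
    if n_leaves is None:
        n_leaves = max(leaves)
    g = nx.Graph()
    centre = "c0"
    pendant = {}
    for s in splits:
        if s.is_pendant:
            (leaf,) = s.side1
            pendant[leaf] = s
    if set(pendant) != set(leaves):
        raise ValueError("split system must contain every pendant split")
    if len(leaves) == 2:
        u, v = leaves
        # a 2-leaf tree has a single edge; both pendant splits name it
        total = lengths[pendant[u]]
        g.add_edge(u, v, length=total)
        return Forest(g, n_leaves=n_leaves, validate=False)
    for leaf in leaves:
        g.add_edge(leaf, centre, length=lengths[pendant[leaf]])
    counter = itertools.count(1)
    internal = sorted((s for s in splits if not s.is_pendant),
                      key=lambda s: (len(s.side1), s.key()))
    for s in internal:
        side = s.side1
        # locate the vertex all of whose `side`-leaf-bearing neighbour
        # subtrees attach; pull those subtrees onto a new vertex
        host = None
        for v in list(g.nodes):
            if isinstance(v, int):
                continue
            groups = []
            for nb in g.neighbors(v):
                below = _leaves_beyond(g, v, nb)
                groups.append((nb, below))
            inside = [nb for nb, below in groups if below <= side]
            covered = frozenset().union(*(below for nb, below in groups if below <= side)) \
                if inside else frozenset()
            if covered == side:
                host = v
                moved = inside
                break
        if host is None:
            raise ValueError(f"incompatible split system at {s!r}")
        new = f"c{next(counter)}"
        for nb in moved:
            attrs = g.edges[host, nb]
            g.remove_edge(host, nb)
            g.add_edge(new, nb, **attrs)
        g.add_edge(host, new, length=lengths[s])
    return Forest(g, n_leaves=n_leaves, validate=False)


def _leaves_beyond(g: nx.Graph, v, nb) -> frozenset[int]:
    """Leaf labels in the component of ``nb`` after removing edge (v, nb)."""
    seen = {v, nb}
    stack = [nb]
    out = set()
    while stack:
        x = stack.pop()
        if isinstance(x, int):
            out.add(x)
        for y in g.neighbors(x):
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Forest
# ---------------------------------------------------------------------------

class Forest:
    """A labelled-leaf forest: the representative object of wald space.

    Vertices of the underlying graph are either integer leaf labels
    ``1..N`` (degree 1) or unlabelled internal vertices (strings, degree
    >= 3).  Each edge carries a ``length`` attribute in ``[0, inf]``.
    """

    def __init__(self, graph: nx.Graph, n_leaves: int,
                 validate: bool = True, allow_zero_pendant: bool = False):
        self.graph = graph
        self.n_leaves = int(n_leaves)
        if validate:
            self.validate(allow_zero_pendant=allow_zero_pendant)

    # -- basic accessors ----------------------------------------------------
    @property
    def leaves(self) -> list[int]:
        return list(range(1, self.n_leaves + 1))

    def edges(self) -> list[tuple]:
        return list(self.graph.edges)

    def edge_length(self, e: tuple) -> float:
        return self.graph.edges[e]["length"]

    def edge_weight(self, e: tuple) -> float:
        return length_to_weight(self.edge_length(e))

    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.graph)

    def is_single_tree(self) -> bool:
        return self.n_components == 1

    def is_resolved(self) -> bool:
        """True iff the forest is one tree with the full 2N-3 edges."""
        return (self.is_single_tree()
                and self.graph.number_of_edges() == 2 * self.n_leaves - 3)

    def copy(self) -> "Forest":
        return Forest(self.graph.copy(), self.n_leaves, validate=False)

    # -- splits and coordinates ---------------------------------------------
    def split_of_edge(self, e: tuple) -> Split:
        u, v = e
        comp_leaves = _leaves_beyond(self.graph, u, v) | _leaves_beyond(self.graph, v, u)
        side = _leaves_beyond(self.graph, u, v)
        return Split.of(side, comp_leaves - side)

    def topology(self) -> Topology:
        if not self.is_single_tree():
            raise ValueError("topology is defined for single trees only")
        return Topology(frozenset(self.split_of_edge(e) for e in self.edges()))

    def edge_order(self) -> list[tuple]:
        """Edges in canonical coordinate order (pendant by leaf label, then
        internal splits lexicographically) for resolved-tree coordinates."""
        return sorted(self.edges(), key=lambda e: self.split_of_edge(e).key())

    def length_vector(self) -> np.ndarray:
        return np.array([self.edge_length(e) for e in self.edge_order()])

    def with_lengths(self, lengths: Sequence[float]) -> "Forest":
        """Copy of this forest with lengths replaced, in edge_order()."""
        g = self.graph.copy()
        for e, l in zip(self.edge_order(), lengths, strict=True):
            g.edges[e]["length"] = float(l)
        return Forest(g, self.n_leaves, validate=False)

    # -- validation ----------------------------------------------------------
    def validate(self, allow_zero_pendant: bool = False) -> None:
        g = self.graph
        labels = [v for v in g.nodes if isinstance(v, int)]
        if sorted(labels) != list(range(1, self.n_leaves + 1)):
            raise ValueError(
                f"leaves must be labelled 1..{self.n_leaves}, got {sorted(labels)}")
        for v in g.nodes:
            d = g.degree(v)
            if isinstance(v, int):
                if d > 1:
                    raise ValueError(f"leaf {v} has degree {d} > 1")
            elif d in (0, 1, 2):
                raise ValueError(f"unlabelled vertex {v!r} has degree {d}")
        for e in g.edges:
            l = g.edges[e]["length"]
            if not l >= 0:
                raise ValueError(f"edge {e} has negative length {l}")
            if not allow_zero_pendant and l == 0 and any(
                    isinstance(x, int) for x in e):
                raise ValueError(f"pendant edge {e} has zero length")
        self._check_no_coincident_leaves()

    def _check_no_coincident_leaves(self) -> None:
        """Every same-component leaf pair needs a positive-weight path edge."""
        zero = self.graph.edge_subgraph(
            [e for e in self.graph.edges if self.graph.edges[e]["length"] == 0]
        )
        for comp in nx.connected_components(zero):
            ls = sorted(v for v in comp if isinstance(v, int))
            if len(ls) > 1:
                raise ValueError(
                    f"coincident leaves {ls[0]} and {ls[1]}: "
                    "all edges on their path have weight zero")

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Forest(n_leaves={self.n_leaves}, "
                f"components={self.n_components}, "
                f"edges={self.graph.number_of_edges()})")


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str, n_leaves: int | None = None) -> Forest:
    """Parse one or more Newick statements into a Forest.

    Leaf labels must be distinct positive integers; branch lengths are
    non-negative numbers or the token ``inf``.  Several ``;``-terminated
    statements (one per tree component) form a single forest.  Rooted input
    is read as unrooted: any unlabelled degree-2 vertex is suppressed with
    the two adjacent lengths summed.
    """
    import dendropy

    statements = [s.strip() for s in text.split(";") if s.strip()]
    if not statements:
        raise ValueError("no Newick statement found")
    g = nx.Graph()
    fresh = itertools.count()
    seen_labels: set[int] = set()
    for stmt in statements:
        _add_component(g, stmt, fresh, seen_labels)
    if n_leaves is None:
        n_leaves = max(seen_labels)
    if seen_labels != set(range(1, n_leaves + 1)):
        raise ValueError(
            f"leaf labels must be 1..{n_leaves}, got {sorted(seen_labels)}")
    _suppress_degree_two(g)
    return Forest(g, n_leaves=n_leaves)


def _parse_length(raw) -> float:
    if raw is None:
        return 0.0
    l = float(raw)
    if math.isnan(l) or l < 0:
        raise ValueError(f"invalid branch length {raw!r}")
    return l


def _add_component(g: nx.Graph, stmt: str, fresh, seen: set[int]) -> None:
    import dendropy

    bare = stmt.strip()
    if "(" not in bare:  # isolated leaf such as "3;"
        label = bare.split(":")[0].strip()
        leaf = _leaf_label(label, seen)
        g.add_node(leaf)
        return
    try:
        tree = dendropy.Tree.get(
            data=bare + ";", schema="newick",
            suppress_internal_node_taxa=True, preserve_underscores=True)
    except Exception as exc:
        msg = str(exc)
        if "uplicate" in msg:
            raise ValueError(f"duplicate leaf label: {msg}") from exc
        raise ValueError(f"malformed Newick statement: {msg}") from exc
    node_id = {}
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon is not None else None
            node_id[nd] = _leaf_label(label, seen)
            g.add_node(node_id[nd])
        else:
            node_id[nd] = f"v{next(fresh)}"
            g.add_node(node_id[nd])
        if nd.parent_node is not None:
            g.add_edge(node_id[nd.parent_node], node_id[nd],
                       length=_parse_length(nd.edge.length))


def _leaf_label(label, seen: set[int]) -> int:
    if label is None:
        raise ValueError("leaf without a label")
    try:
        leaf = int(str(label))
    except ValueError:
        raise ValueError(f"leaf labels must be integers, got {label!r}") from None
    if leaf < 1:
        raise ValueError(f"leaf labels must be positive, got {leaf}")
    if leaf in seen:
        raise ValueError(f"duplicate leaf label {leaf}")
    seen.add(leaf)
    return leaf


def _suppress_degree_two(g: nx.Graph) -> None:
    """Remove unlabelled degree-2 vertices, summing adjacent lengths."""
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            if isinstance(v, int) or g.degree(v) != 2:
                continue
            (a, b) = list(g.neighbors(v))
            la = g.edges[v, a]["length"]
            lb = g.edges[v, b]["length"]
            g.remove_node(v)
            g.add_edge(a, b, length=la + lb)
            changed = True


def _fmt_len(l: float) -> str:
    return "inf" if math.isinf(l) else f"{l:.12g}"


def write_newick(forest: Forest) -> str:
    """Serialize a forest as one Newick statement per component.

    Deterministic: components are ordered by smallest leaf label, children
    by their smallest descendant label.  A 2-leaf tree is written with the
    single edge length halved across the two pendant branches.
    """
    g = forest.graph
    out = []
    comps = sorted(nx.connected_components(g),
                   key=lambda c: min(v for v in c if isinstance(v, int)))
    for comp in comps:
        leaves = sorted(v for v in comp if isinstance(v, int))
        if len(leaves) == 1:
            out.append(f"{leaves[0]};")
            continue
        if len(leaves) == 2:
            u, v = leaves
            l = g.edges[u, v]["length"] / 2.0
            out.append(f"({u}:{_fmt_len(l)},{v}:{_fmt_len(l)});")
            continue
        root = next(x for x in g.neighbors(leaves[0]) if not isinstance(x, int))
        out.append(_newick_subtree(g, root, None)[1] + ";")
    return "\n".join(out)


def _newick_subtree(g: nx.Graph, v, parent) -> tuple[int, str]:
    """Return (smallest descendant label, newick text without length)."""
    if isinstance(v, int):
        return v, str(v)
    parts = []
    for nb in g.neighbors(v):
        if nb == parent:
            continue
        key, text = _newick_subtree(g, nb, v)
        parts.append((key, text + ":" + _fmt_len(g.edges[v, nb]["length"])))
    parts.sort()
    return parts[0][0], "(" + ",".join(t for _, t in parts) + ")"


# ---------------------------------------------------------------------------
# leaf distances and split matrices
# ---------------------------------------------------------------------------

def leaf_distance_matrix(forest: Forest) -> np.ndarray:
    """Matrix of path lengths between leaves; +inf across components."""
    n = forest.n_leaves
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for comp in forest.components():
        ls = sorted(v for v in comp if isinstance(v, int))
        for u, v in itertools.combinations(ls, 2):
            d[u - 1, v - 1] = d[v - 1, u - 1] = 0.0
    for e in forest.edges():
        sigma = split_matrix(forest, e)
        l = forest.edge_length(e)
        mask = sigma.astype(bool)
        d[mask] += l
    return d


def split_matrix(forest: Forest, edge: tuple) -> np.ndarray:
    """N x N 0/1 indicator of whether ``edge`` separates each leaf pair."""
    u, v = edge
    if not forest.graph.has_edge(u, v):
        raise ValueError(f"edge {edge} not in forest")
    side = _leaves_beyond(forest.graph, u, v)
    other = _leaves_beyond(forest.graph, v, u)
    n = forest.n_leaves
    sigma = np.zeros((n, n), dtype=int)
    for a in side:
        for b in other:
            sigma[a - 1, b - 1] = sigma[b - 1, a - 1] = 1
    return sigma


def split_matrices(forest: Forest, edges: Sequence[tuple] | None = None) -> list[np.ndarray]:
    if edges is None:
        edges = forest.edge_order()
    return [split_matrix(forest, e) for e in edges]


# ---------------------------------------------------------------------------
# wald-space equivalence
# ---------------------------------------------------------------------------

def canonicalize(forest: Forest) -> Forest:
    """Reduce a forest to the canonical representative of its wald class.

    Applies the BHV boundary rule (contract internal weight-0 edges) and the
    boundary-at-infinity rule (delete weight-1 edges, suppress resulting
    unlabelled degree-2 vertices with additive length merge) until neither
    applies.
    """
    g = forest.graph.copy()
    fresh = itertools.count(10**6)
    changed = True
    while changed:
        changed = False
        # BHV rule: contract internal zero-length edges
        for e in list(g.edges):
            u, v = e
            if isinstance(u, int) or isinstance(v, int):
                continue
            if g.edges[e]["length"] == 0:
                _contract(g, u, v, fresh)
                changed = True
                break
        if changed:
            continue
        # boundary at infinity: delete infinite edges
        for e in list(g.edges):
            if math.isinf(g.edges[e]["length"]):
                g.remove_edge(*e)
                changed = True
                break
        if changed:
            _cleanup(g)
    _cleanup(g)
    out = Forest(g, forest.n_leaves, validate=False)
    out.validate(allow_zero_pendant=True)
    return out


def _contract(g: nx.Graph, u, v, fresh) -> None:
    new = f"m{next(fresh)}"
    g.add_node(new)
    for x in (u, v):
        for nb in list(g.neighbors(x)):
            if nb in (u, v):
                continue
            l = g.edges[x, nb]["length"]
            if g.has_edge(new, nb):  # parallel edge cannot occur in trees
                raise ValueError("contraction produced a multi-edge")
            g.add_edge(new, nb, length=l)
    g.remove_node(u)
    g.remove_node(v)


def _cleanup(g: nx.Graph) -> None:
    """Drop dangling unlabelled vertices; suppress unlabelled degree-2
    vertices with additive length merge (weights combine as a+b-ab)."""
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            if isinstance(v, int):
                continue
            d = g.degree(v)
            if d == 0 or d == 1:
                g.remove_node(v)
                changed = True
            elif d == 2:
                a, b = g.neighbors(v)
                la = g.edges[v, a]["length"]
                lb = g.edges[v, b]["length"]
                g.remove_node(v)
                g.add_edge(a, b, length=la + lb)
                changed = True


def _canonical_signature(forest: Forest, digits: int = 9):
    """Hashable description of a canonical forest: per component, the leaf
    set plus the (split, rounded length) pairs of its edges."""
    comps = []
    for comp in forest.components():
        ls = frozenset(v for v in comp if isinstance(v, int))
        entries = []
        for e in forest.graph.subgraph(comp).edges:
            s = forest.split_of_edge(e)
            entries.append((s.key(), round(forest.edge_length(e), digits)))
        comps.append((tuple(sorted(ls)), tuple(sorted(entries))))
    return tuple(sorted(comps))


def forests_equivalent(f1: Forest, f2: Forest, tol: float = LENGTH_TOL) -> bool:
    """Wald-space equivalence: equality of canonical representatives."""
    if f1.n_leaves != f2.n_leaves:
        raise ValueError("forests must share the same leaf set")
    c1, c2 = canonicalize(f1), canonicalize(f2)
    p1 = {frozenset(v for v in c if isinstance(v, int)) for c in c1.components()}
    p2 = {frozenset(v for v in c if isinstance(v, int)) for c in c2.components()}
    if p1 != p2:
        return False
    m1 = _split_length_map(c1)
    m2 = _split_length_map(c2)
    if set(m1) != set(m2):
        return False
    return all(abs(m1[k] - m2[k]) <= tol for k in m1)


def _split_length_map(forest: Forest) -> dict:
    out = {}
    for comp in forest.components():
        for e in forest.graph.subgraph(comp).edges:
            out[forest.split_of_edge(e).key()] = forest.edge_length(e)
    return out


# ---------------------------------------------------------------------------
# topology combinatorics
# ---------------------------------------------------------------------------

def enumerate_topologies(n_leaves: int) -> list[Topology]:
    """All (2N-5)!! fully resolved unrooted topologies on leaves 1..N.

    Built by sequential leaf insertion onto every edge; deterministic order.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    if n_leaves > MAX_ENUM_LEAVES:
        raise ValueError(f"enumeration guarded at N <= {MAX_ENUM_LEAVES}")
    # trees as frozensets of edges over nodes; internal nodes negative ints
    base = frozenset([(1, -1), (2, -1), (3, -1)])
    trees = [base]
    for leaf in range(4, n_leaves + 1):
        new_internal = -(leaf - 2)
        nxt = []
        for t in trees:
            for e in sorted(t):
                u, v = e
                rest = t - {e}
                nxt.append(frozenset(rest | {(u, new_internal),
                                             (v, new_internal),
                                             (leaf, new_internal)}))
            # keep insertion deterministic: edges iterated in sorted order
        trees = nxt
    out = []
    for t in trees:
        g = nx.Graph()
        for u, v in t:
            g.add_edge(u, v, length=1.0)
        f = Forest(_relabel_internal(g), n_leaves, validate=False)
        out.append(f.topology())
    out.sort(key=Topology.sort_key)
    return out


def _relabel_internal(g: nx.Graph) -> nx.Graph:
    mapping = {v: (v if (isinstance(v, int) and v > 0) else f"i{-v}")
               for v in g.nodes}
    return nx.relabel_nodes(g, mapping)


def nni_neighbors(topology: Topology, internal_split: Split) -> tuple[Topology, Topology]:
    """The two alternative resolutions across an internal split.

    Contracting the internal edge gives a degree-4 vertex with four hanging
    subtrees A, B | C, D; the neighbours re-pair them as A, C | B, D and
    A, D | B, C.  All other splits are preserved.
    """
    if internal_split.is_pendant:
        raise ValueError("NNI is defined for internal splits only")
    if internal_split not in topology.splits:
        raise ValueError("split not in topology")
    if not topology.resolved:
        raise ValueError("topology must be fully resolved")
    tree = topology.to_tree({s: 1.0 for s in topology.splits})
    g = tree.graph
    # find the edge realizing the split
    edge = next(e for e in tree.edges()
                if tree.split_of_edge(e) == internal_split)
    u, v = edge
    subs_u = [_leaves_beyond(g, u, nb) for nb in g.neighbors(u) if nb != v]
    subs_v = [_leaves_beyond(g, v, nb) for nb in g.neighbors(v) if nb != u]
    A, B = subs_u
    C, D = subs_v
    others = topology.splits - {internal_split}
    n1 = Topology(frozenset(others | {Split.of(A | C, B | D)}))
    n2 = Topology(frozenset(others | {Split.of(A | D, B | C)}))
    return n1, n2
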