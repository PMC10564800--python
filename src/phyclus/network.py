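"""Rooted phylogenetic networks as labeled DAGs, and their structural calculus.

A *network* here is the most general object of the theory: a finite DAG with a
unique root from which every vertex is reachable.  Leaves are the outdegree-0
vertices and carry the taxon labels X; a vertex is a *hybrid* if its indegree
exceeds 1 and a *tree vertex* otherwise.  All the classical refinements
(phylogenetic, separated, binary, tree-child, normal, tree-based, galled,
level-k, ...) are predicates on this one data model, evaluated here directly
from their definitions.

The partial order ``u <= v`` ("u descends from v") is reachability: there is a
directed path from v down to u, possibly empty.  Descendant sets are cached
per instance; networks are treated as immutable after construction (the
rewrite operations in :mod:`phyclus.transform` always build fresh networks).
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple

import networkx as nx
from networkx.algorithms.bipartite.matching import hopcroft_karp_matching

from .errors import (
    CyclicGraph,
    LeafLabelMismatch,
    MultipleRoots,
    UnknownArc,
    UnknownVertex,
    UnreachableVertex,
)

VertexId = str
Arc = Tuple[VertexId, VertexId]


@dataclass(frozen=True)
class Block:
    """A maximal biconnected subgraph of the underlying undirected graph.

    ``max_vertex`` is the unique ancestor-maximal vertex of the block and
    ``terminal_vertices`` are its ancestor-minimal ones; in a non-trivial
    block every terminal vertex has indegree >= 2 within the block.
    """

    vertices: FrozenSet[VertexId]
    arcs: FrozenSet[Arc]
    max_vertex: VertexId
    terminal_vertices: FrozenSet[VertexId]
    nontrivial: bool

    @property
    def interior(self) -> FrozenSet[VertexId]:
        """B0: the block minus its maximum and its terminal vertices."""
        return self.vertices - {self.max_vertex} - self.terminal_vertices


@dataclass(frozen=True)
class StructuralFlags:
    phylogenetic: bool
    separated: bool
    binary: bool
    quasi_binary: bool
    conventional: bool
    shortcut_free: bool


class Network:
    """A rooted DAG with labeled leaves.

    Construct via :func:`build_network` (which validates) or the convenience
    classmethod :meth:`from_arcs`.  A single isolated vertex is a valid
    network: its root is simultaneously its only leaf.
    """

    def __init__(self, g: nx.DiGraph, leaf_labels: Dict[VertexId, str]):
        self._g = g
        self.leaf_labels: Dict[VertexId, str] = dict(leaf_labels)
        self._label_to_leaf = {lab: v for v, lab in self.leaf_labels.items()}
        self._validate()

    # -- construction ---------------------------------------------------------
    @classmethod
    def from_arcs(
        cls,
        arcs: Iterable[Arc],
        leaf_labels: Optional[Mapping[VertexId, str]] = None,
        vertices: Iterable[VertexId] = (),
    ) -> "Network":
        g = nx.DiGraph()
        g.add_nodes_from(str(v) for v in vertices)
        for u, v in arcs:
            g.add_edge(str(u), str(v))
        leaves = {v for v in g if g.out_degree(v) == 0}
        if leaf_labels is None:
            labels = {v: v for v in leaves}
        else:
            labels = {str(v): str(lab) for v, lab in leaf_labels.items()}
            for v in leaves - set(labels):
                labels[v] = v  # default: a leaf is labeled by its own id
        return cls(g, labels)

    def _validate(self) -> None:
        g = self._g
        if len(g) == 0:
            raise UnreachableVertex("empty networks are not allowed")
        for v in g:
            if g.has_edge(v, v):
                raise CyclicGraph(f"self-loop at {v!r}")
        if not nx.is_directed_acyclic_graph(g):
            raise CyclicGraph("arc set contains a directed cycle")
        roots = [v for v in g if g.in_degree(v) == 0]
        if len(roots) != 1:
            raise MultipleRoots(f"expected a unique root, found {sorted(roots)}")
        self._root = roots[0]
        reachable = {self._root} | nx.descendants(g, self._root)
        if reachable != set(g):
            missing = sorted(set(g) - reachable)
            raise UnreachableVertex(f"vertices not reachable from root: {missing}")
        leaves = {v for v in g if g.out_degree(v) == 0}
        if set(self.leaf_labels) != leaves:
            raise LeafLabelMismatch(
                f"leaf labels given for {sorted(self.leaf_labels)}, "
                f"but leaves are {sorted(leaves)}"
            )
        if len(set(self.leaf_labels.values())) != len(self.leaf_labels):
            raise LeafLabelMismatch("leaf labels are not pairwise distinct")

    # -- basic accessors -------------------------------------------------------
    @property
    def root(self) -> VertexId:
        return self._root

    @property
    def vertices(self) -> Set[VertexId]:
        return set(self._g.nodes)

    @property
    def arcs(self) -> Set[Arc]:
        return set(self._g.edges)

    @property
    def leaves(self) -> Set[VertexId]:
        return set(self.leaf_labels)

    @property
    def labels(self) -> FrozenSet[str]:
        """The taxon set X."""
        return frozenset(self.leaf_labels.values())

    def leaf_of(self, label: str) -> VertexId:
        try:
            return self._label_to_leaf[label]
        except KeyError:
            raise UnknownVertex(f"no leaf labeled {label!r}") from None

    def parents(self, v: VertexId) -> Set[VertexId]:
        self._check_vertex(v)
        return set(self._g.predecessors(v))

    def children(self, v: VertexId) -> Set[VertexId]:
        self._check_vertex(v)
        return set(self._g.successors(v))

    def indeg(self, v: VertexId) -> int:
        self._check_vertex(v)
        return self._g.in_degree(v)

    def outdeg(self, v: VertexId) -> int:
        self._check_vertex(v)
        return self._g.out_degree(v)

    def is_leaf(self, v: VertexId) -> bool:
        return self.outdeg(v) == 0

    def is_hybrid(self, v: VertexId) -> bool:
        return self.indeg(v) > 1

    def is_tree_vertex(self, v: VertexId) -> bool:
        return self.indeg(v) <= 1

    def role(self, v: VertexId) -> str:
        """'leaf', 'tree' or 'hybrid'.  A leaf counts as 'leaf' even when it
        has indegree > 1 (a hybrid leaf)."""
        if self.is_leaf(v):
            return "leaf"
        return "hybrid" if self.is_hybrid(v) else "tree"

    @property
    def hybrids(self) -> Set[VertexId]:
        return {v for v in self._g if self.is_hybrid(v)}

    @property
    def inner_vertices(self) -> Set[VertexId]:
        return self.vertices - self.leaves

    def _check_vertex(self, v: VertexId) -> None:
        if v not in self._g:
            raise UnknownVertex(f"unknown vertex {v!r}")

    def _check_arc(self, arc: Arc) -> None:
        if not self._g.has_edge(*arc):
            raise UnknownArc(f"unknown arc {arc!r}")

    def __len__(self) -> int:
        return len(self._g)

    def copy_graph(self) -> nx.DiGraph:
        return self._g.copy()

    # -- order and clusters ----------------------------------------------------
    @cached_property
    def _topo(self) -> List[VertexId]:
        return list(nx.topological_sort(self._g))

    @cached_property
    def _desc(self) -> Dict[VertexId, FrozenSet[VertexId]]:
        """Reflexive down-sets: descendants-or-self of every vertex."""
        desc: Dict[VertexId, FrozenSet[VertexId]] = {}
        for v in reversed(self._topo):
            s = {v}
            for c in self._g.successors(v):
                s |= desc[c]
            desc[v] = frozenset(s)
        return desc

    def descends(self, u: VertexId, v: VertexId) -> bool:
        """u <= v in the ancestor order (reflexive)."""
        self._check_vertex(u)
        self._check_vertex(v)
        return u in self._desc[v]

    def comparable(self, u: VertexId, v: VertexId) -> bool:
        return self.descends(u, v) or self.descends(v, u)

    @cached_property
    def _cluster_map(self) -> Dict[VertexId, FrozenSet[str]]:
        cm: Dict[VertexId, FrozenSet[str]] = {}
        for v in reversed(self._topo):
            if self.is_leaf(v):
                cm[v] = frozenset({self.leaf_labels[v]})
            else:
                s: Set[str] = set()
                for c in self._g.successors(v):
                    s |= cm[c]
                cm[v] = frozenset(s)
        return cm

    def cluster(self, v: VertexId) -> FrozenSet[str]:
        """C(v): the set of leaf labels reachable from v."""
        self._check_vertex(v)
        return self._cluster_map[v]

    # -- blocks ----------------------------------------------------------------
    @cached_property
    def _blocks(self) -> Tuple[Block, ...]:
        g = self._g
        und = nx.Graph(g.to_undirected(as_view=False))
        result: List[Block] = []
        if len(g) == 1:
            v = self._root
            return (
                Block(frozenset({v}), frozenset(), v, frozenset({v}), False),
            )
        for comp in nx.biconnected_components(und):
            comp = frozenset(comp)
            arcs = frozenset(
                (u, v) for u, v in g.edges if u in comp and v in comp
            )
            maxima = [v for v in comp if not any(p in comp for p in g.predecessors(v))]
            minima = frozenset(
                v for v in comp if not any(c in comp for c in g.successors(v))
            )
            assert len(maxima) == 1, "a block must have a unique maximal vertex"
            nontrivial = len(comp) >= 3
            result.append(Block(comp, arcs, maxima[0], minima, nontrivial))
        return tuple(result)

    def blocks(self) -> List[Block]:
        """All blocks (maximal biconnected subgraphs); pairwise arc-disjoint."""
        return list(self._blocks)

    def nontrivial_blocks(self) -> List[Block]:
        return [b for b in self._blocks if b.nontrivial]

    def block_of_hybrid(self, w: VertexId) -> Block:
        """The unique block properly containing the hybrid vertex w (the one
        in which w is not the block maximum)."""
        for b in self._blocks:
            if w in b.vertices and w != b.max_vertex:
                return b
        raise UnknownVertex(f"{w!r} is not properly contained in any block")

    # -- shortcuts and level ---------------------------------------------------
    def is_shortcut(self, arc: Arc) -> bool:
        """(u, w) is a shortcut if some other child of u is a strict ancestor
        of w, i.e. a directed u->w path avoids the arc."""
        self._check_arc(arc)
        u, w = arc
        return any(
            w in self._desc[v] for v in self._g.successors(u) if v != w
        )

    def shortcuts(self) -> Set[Arc]:
        return {a for a in self._g.edges if self.is_shortcut(a)}

    def is_shortcut_free(self) -> bool:
        return not any(self.is_shortcut(a) for a in self._g.edges)

    def level(self) -> int:
        """max over blocks B of the number of hybrid vertices in B other than
        max B; 0 for trees."""
        lvl = 0
        for b in self._blocks:
            k = sum(
                1 for v in b.vertices if v != b.max_vertex and self.is_hybrid(v)
            )
            lvl = max(lvl, k)
        return lvl

    # -- structural flags ------------------------------------------------------
    def is_phylogenetic(self) -> bool:
        return not any(
            self.outdeg(v) == 1 and self.indeg(v) <= 1 for v in self._g
        )

    def is_separated(self) -> bool:
        return all(self.outdeg(v) == 1 for v in self.hybrids)

    def is_binary(self) -> bool:
        for v in self._g:
            if self.is_hybrid(v):
                if self.indeg(v) != 2 or self.outdeg(v) != 1:
                    return False
            elif not self.is_leaf(v) and self.outdeg(v) != 2:
                return False
        return True

    def is_quasi_binary(self) -> bool:
        if not all(
            self.indeg(w) == 2 and self.outdeg(w) == 1 for w in self.hybrids
        ):
            return False
        return all(
            self.outdeg(b.max_vertex) == 2 for b in self.nontrivial_blocks()
        )

    def is_conventional(self) -> bool:
        if not all(self.indeg(x) <= 1 for x in self.leaves):
            return False
        for w in self.hybrids:
            n_blocks = sum(
                1 for b in self.nontrivial_blocks() if w in b.vertices
            )
            if n_blocks != 1:
                return False
        return True

    def structural_flags(self) -> StructuralFlags:
        return StructuralFlags(
            phylogenetic=self.is_phylogenetic(),
            separated=self.is_separated(),
            binary=self.is_binary(),
            quasi_binary=self.is_quasi_binary(),
            conventional=self.is_conventional(),
            shortcut_free=self.is_shortcut_free(),
        )

    # -- tree-child / normal / tree-based / galled -----------------------------
    def is_tree_child(self) -> bool:
        """Every inner vertex has a child of indegree 1."""
        return all(
            any(self.indeg(c) == 1 for c in self.children(v))
            for v in self.inner_vertices
        )

    def is_normal(self) -> bool:
        return self.is_tree_child() and self.is_shortcut_free()

    @property
    def omnians(self) -> Set[VertexId]:
        """Inner vertices all of whose children are hybrid."""
        return {
            v
            for v in self.inner_vertices
            if all(self.is_hybrid(c) for c in self.children(v))
        }

    def is_tree_based(self, witness: bool = False):
        """Tree-based: a rooted spanning tree with leaf set exactly X exists.

        Choosing one in-arc per non-root vertex always yields a spanning tree;
        an inner vertex of N degenerates to a dummy leaf exactly when it is an
        omnian none of whose (hybrid) children selected it.  Hence N is
        tree-based iff the bipartite graph omnians-vs-their-children admits a
        matching saturating all omnians.  Ties in the witness tree are broken
        by lexicographic vertex id.
        """
        omn = sorted(self.omnians)
        left = ["L#" + v for v in omn]
        bg = nx.Graph()
        bg.add_nodes_from(left, bipartite=0)
        for v in omn:
            for c in sorted(self.children(v)):
                bg.add_node("R#" + c, bipartite=1)
                bg.add_edge("L#" + v, "R#" + c)
        matching = (
            hopcroft_karp_matching(bg, top_nodes=left) if left else {}
        )
        matched = {v for v in omn if ("L#" + v) in matching}
        based = len(matched) == len(omn)
        if not witness:
            return based
        if not based:
            return False, None
        # Build the witness spanning tree: every tree vertex keeps its unique
        # in-arc; every hybrid selects its matched omnian parent if any,
        # otherwise the lexicographically smallest parent.
        hybrid_choice: Dict[VertexId, VertexId] = {}
        for v in omn:
            c = matching["L#" + v][2:]
            hybrid_choice.setdefault(c, v)
        tree_arcs = []
        for v in self._g:
            if v == self._root:
                continue
            if self.indeg(v) == 1:
                (p,) = self.parents(v)
            elif v in hybrid_choice:
                p = hybrid_choice[v]
            else:
                p = min(self.parents(v))
            tree_arcs.append((p, v))
        return True, tree_arcs

    def is_galled_tree(self) -> bool:
        """Every non-trivial block is an undirected cycle."""
        for b in self.nontrivial_blocks():
            if len(b.arcs) != len(b.vertices):
                return False
            deg: Dict[VertexId, int] = {v: 0 for v in b.vertices}
            for u, v in b.arcs:
                deg[u] += 1
                deg[v] += 1
            if any(d != 2 for d in deg.values()):
                return False
        return True

    # -- misc ------------------------------------------------------------------
    def relabeled(self, mapping: Mapping[VertexId, VertexId]) -> "Network":
        """A copy with vertex ids renamed by ``mapping`` (ids not in the
        mapping are kept).  Leaf labels are preserved."""
        m = {v: mapping.get(v, v) for v in self._g}
        if len(set(m.values())) != len(m):
            raise ValueError("relabeling is not injective")
        g = nx.relabel_nodes(self._g, m, copy=True)
        labels = {m[v]: lab for v, lab in self.leaf_labels.items()}
        return Network(g, labels)

    def __repr__(self) -> str:
        return (
            f"Network({len(self._g)} vertices, {self._g.number_of_edges()} arcs, "
            f"X={sorted(self.labels)})"
        )


def build_network(
    arcs: Iterable[Arc],
    leaf_labels: Optional[Mapping[VertexId, str]] = None,
    vertices: Iterable[VertexId] = (),
) -> Network:
    """Validate and build a network from an arc list.

    Rejects multiple roots, directed cycles, unreachable vertices, and leaf
    label maps that are not bijections onto the outdegree-0 vertices.
    Parallel arcs collapse to a single arc (the arc set is a set of ordered
    pairs); an isolated vertex may be passed through ``vertices`` to build a
    single-vertex network.
    """
    return Network.from_arcs(arcs, leaf_labels, vertices)


def descends(n: Network, u: VertexId, v: VertexId) -> bool:
    return n.descends(u, v)


def blocks(n: Network) -> List[Block]:
    return n.blocks()


def is_shortcut(n: Network, arc: Arc) -> bool:
    return n.is_shortcut(arc)


def shortcuts(n: Network) -> Set[Arc]:
    return n.shortcuts()


def level(n: Network) -> int:
    return n.level()


def structural_flags(n: Network) -> StructuralFlags:
    return n.structural_flags()


def is_tree_child(n: Network) -> bool:
    return n.is_tree_child()


def is_normal(n: Network) -> bool:
    return n.is_normal()


def is_tree_based(n: Network, witness: bool = False):
    return n.is_tree_based(witness=witness)


def is_galled_tree(n: Network) -> bool:
    return n.is_galled_tree()
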