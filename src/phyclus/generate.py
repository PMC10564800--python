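"""Fixture catalog, seeded random generators, and brute-force oracles.

The fixture networks and clustering systems reproduce the small worked
examples used throughout the theory (the four-vertex diamond block, the
rooted K_{2,2} violating tree-childness, the triangle block with a shortcut,
and the printed clustering systems from the literature on cluster networks
and tree-based networks).

``gen_random_level1`` grows a phylogenetic level-1 network top-down: a random
recursive partition of the leaf set where each node becomes either an
ordinary tree vertex or an undirected cycle (one terminal hybrid, interior
vertices carrying pendant subnetworks).  By construction its output is
separated and tree-child; identical configuration and seed give bit-identical
output.  It emulates the paper-style small study networks, not any natural
distribution over network shapes.
"""
from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Optional, Set, Tuple

import networkx as nx

from .clusters import Cluster, ClusteringSystem, cluster_multiset
from .errors import BadK, InfeasibleConfig, InstanceTooLarge
from .network import Arc, Network, VertexId, build_network
from .transform import isomorphic


# --- fixtures -----------------------------------------------------------------
def fixtures() -> Dict[str, object]:
    """The named examples used across the test battery.

    Networks: F_T3 (three-leaf binary tree), F_D1 (binary diamond block),
    F_P1 (rooted K_{2,2}: two hybrids share both parents), F_SC (triangle
    block whose chord is a shortcut).  Clustering systems: F_CSA = two-leaf
    hierarchy, F_CS11 = seven clusters whose only overlap intersection is
    missing (not closed), F_CS12 = the ten-cluster system whose cluster
    network is not tree-based, F_CS_ALT3 = alternative resolution of the
    three-leaf tree system.
    """
    f_t3 = build_network([("r", "a"), ("r", "3"), ("a", "1"), ("a", "2")])
    f_d1 = build_network(
        [("r", "u"), ("r", "v"), ("u", "y"), ("v", "z"),
         ("u", "h"), ("v", "h"), ("h", "x")]
    )
    f_p1 = build_network(
        [("r", "a"), ("r", "b"), ("a", "h1"), ("b", "h1"),
         ("a", "h2"), ("b", "h2"), ("h1", "x"), ("h2", "y")]
    )
    f_sc = build_network(
        [("r", "u"), ("r", "h"), ("u", "h"), ("u", "y"), ("h", "x")]
    )
    f_csa = ClusteringSystem("ab", [{"a"}, {"b"}, {"a", "b"}])
    f_cs11 = ClusteringSystem(
        "wxyz",
        [{"w"}, {"x"}, {"y"}, {"z"}, {"w", "x", "y"}, {"x", "y", "z"},
         {"w", "x", "y", "z"}],
    )
    f_cs12 = ClusteringSystem(
        "xyzv",
        [{"x"}, {"y"}, {"z"}, {"v"}, {"x", "y"}, {"x", "z"}, {"x", "v"},
         {"y", "z"}, {"y", "v"}, {"x", "y", "z", "v"}],
    )
    f_cs_alt3 = ClusteringSystem(
        "123", [{"1"}, {"2"}, {"3"}, {"2", "3"}, {"1", "2", "3"}]
    )
    return {
        "F_T3": f_t3,
        "F_D1": f_d1,
        "F_P1": f_p1,
        "F_SC": f_sc,
        "F_CSA": f_csa,
        "F_CS11": f_cs11,
        "F_CS12": f_cs12,
        "F_CS_ALT3": f_cs_alt3,
    }


# --- random level-1 generator -------------------------------------------------
@dataclass(frozen=True)
class GeneratorConfig:
    n_leaves: int
    n_blocks: int = 0
    max_block_size: int = 6
    seed: int = 0
    force_binary: bool = False
    force_separated: bool = True
    allow_shortcuts: bool = False

    def __post_init__(self):
        if self.n_leaves < 1:
            raise InfeasibleConfig("need at least one leaf")
        if self.n_blocks < 0:
            raise InfeasibleConfig("n_blocks must be non-negative")
        if self.n_blocks > 0 and self.max_block_size < 3:
            raise InfeasibleConfig("blocks need max_block_size >= 3")


def _capacity(m: int) -> int:
    """Maximum number of nested cycle blocks placeable over m leaves."""
    return max(0, (m - 1) // 2)


def gen_random_level1(cfg: GeneratorConfig) -> Network:
    """A random phylogenetic level-1 network on leaves x1..xn.

    Each block is an undirected cycle with a unique terminal hybrid; cycle
    interior vertices carry pendant subnetworks, so the output is separated,
    tree-child and (without injected shortcuts) galled.  ``force_binary``
    restricts all partitions to two parts, which makes the output binary;
    ``allow_shortcuts`` additionally inserts the chord from a block's maximum
    to its hybrid with probability 1/2 per block (and permits triangles).
    """
    rng = random.Random(cfg.seed)
    leaves = [f"x{i}" for i in range(1, cfg.n_leaves + 1)]
    if cfg.n_blocks > _capacity(cfg.n_leaves):
        raise InfeasibleConfig(
            f"{cfg.n_blocks} blocks do not fit on {cfg.n_leaves} leaves "
            f"(capacity {_capacity(cfg.n_leaves)})"
        )
    min_cycle = 3 if cfg.allow_shortcuts else 4
    if cfg.n_blocks > 0 and cfg.max_block_size < min_cycle:
        raise InfeasibleConfig(
            f"cycles need at least {min_cycle} vertices here "
            f"(max_block_size = {cfg.max_block_size})"
        )
    g = nx.DiGraph()
    counter = itertools.count(1)

    def fresh(prefix: str) -> str:
        return f"{prefix}{next(counter)}"

    def rand_partition(items: List[str], k: int) -> List[List[str]]:
        """Random partition into exactly k non-empty parts."""
        items = items[:]
        rng.shuffle(items)
        parts: List[List[str]] = [[items[i]] for i in range(k)]
        for it in items[k:]:
            parts[rng.randrange(k)].append(it)
        return parts

    def build(part: List[str], required: int, allowed: int) -> int:
        """Grow a subnetwork over ``part``; returns (root placed via outer
        arc by caller) the number of blocks used.  ``required`` blocks must
        be placed here, at most ``allowed`` may be."""
        m = len(part)
        if m == 1:
            g.add_node(part[0])
            build.last_root = part[0]
            return 0
        cap = _capacity(m)
        place_block = (
            allowed > 0
            and m >= 3
            and (required >= cap or (required > 0 and rng.random() < 0.6)
                 or (required == 0 and rng.random() < 0.35))
        )
        if place_block:
            return _build_block(part, required, allowed)
        return _build_tree(part, required, allowed)

    def _split_with_capacity(
        part: List[str], k: int, need: int
    ) -> List[List[str]]:
        for _ in range(30):
            parts = rand_partition(part, k)
            if sum(_capacity(len(p)) for p in parts) >= need:
                return parts
        # deterministic fallback: one big part carries the capacity
        items = sorted(part)
        parts = [[x] for x in items[: k - 1]]
        parts.append(items[k - 1:])
        assert sum(_capacity(len(p)) for p in parts) >= need
        return parts

    def _recurse_parts(
        parts: List[List[str]], required: int, allowed: int
    ) -> Tuple[List[str], int]:
        roots: List[str] = []
        caps = [_capacity(len(p)) for p in parts]
        used_total = 0
        for i, p in enumerate(parts):
            rest_cap = sum(caps[i + 1:])
            req_i = max(0, required - used_total - rest_cap)
            alw_i = min(caps[i], allowed - used_total)
            used = build(p, min(req_i, caps[i]), alw_i)
            roots.append(build.last_root)
            used_total += used
        return roots, used_total

    def _build_tree(part: List[str], required: int, allowed: int) -> int:
        m = len(part)
        if cfg.force_binary or required > 0:
            # two parts keep enough block capacity in one part
            k = 2
        else:
            k = rng.randint(2, min(m, 4))
        parts = _split_with_capacity(part, k, required)
        roots, used = _recurse_parts(parts, required, allowed)
        t = fresh("v")
        for r in roots:
            g.add_edge(t, r)
        build.last_root = t
        return used

    def _build_block(part: List[str], required: int, allowed: int) -> int:
        m = len(part)
        # cap the cycle size so the remaining required blocks still fit into
        # a single pendant part (each nested block needs two extra leaves)
        s_max = min(cfg.max_block_size, m + 3 - 2 * max(required, 1))
        s = rng.randint(min_cycle, max(min_cycle, s_max))
        n_parts = s - 1  # one per interior vertex, plus the hybrid's child
        parts = _split_with_capacity(part, n_parts, required - 1)
        h_index = rng.randrange(n_parts)
        roots, used = _recurse_parts(parts, required - 1, allowed - 1)
        t = fresh("v")
        h = fresh("h")
        interior_roots = [r for i, r in enumerate(roots) if i != h_index]
        n_interior = s - 2
        if n_interior == 1:
            arm_a, arm_b = 1, 0  # triangle: the chord (t, h) is a shortcut
        else:
            arm_a = rng.randint(1, n_interior - 1)
            arm_b = n_interior - arm_a
        arm_vertices = [fresh("v") for _ in range(n_interior)]
        chain_a = arm_vertices[:arm_a]
        chain_b = arm_vertices[arm_a:]
        for chain in (chain_a, chain_b):
            prev = t
            for w in chain:
                g.add_edge(prev, w)
                prev = w
            g.add_edge(prev, h)
        for w, r in zip(arm_vertices, interior_roots):
            g.add_edge(w, r)
        g.add_edge(h, roots[h_index])
        build.last_root = t
        return used + 1

    if cfg.n_leaves == 1 and cfg.n_blocks == 0:
        return build_network([], vertices=leaves)
    build(leaves, cfg.n_blocks, cfg.n_blocks)
    labels = {x: x for x in leaves}
    net = build_network(list(g.edges), labels)
    if cfg.allow_shortcuts:
        extra: List[Arc] = []
        for b in net.nontrivial_blocks():
            (h,) = [
                v for v in b.vertices
                if v != b.max_vertex and net.is_hybrid(v)
            ]
            if (b.max_vertex, h) not in net.arcs and rng.random() < 0.5:
                extra.append((b.max_vertex, h))
        if extra:
            net = build_network(list(net.arcs) + extra, labels)
    if cfg.force_separated:
        assert net.is_separated()
    return net


# --- the complete-bipartite hierarchy construction ----------------------------
def gen_lemma15(n: int, k: int) -> Network:
    """A phylogenetic shortcut-free level-k network on n leaves whose
    clustering system is nevertheless a hierarchy: a star tree on stems
    l1..ln whose first k stems are joined to new leaves x1..xk by a complete
    bipartite graph.  Level is exactly k (not k-1); k = 0 gives the plain
    star."""
    if n < 1:
        raise BadK("need n >= 1")
    if k == 0:
        if n == 1:
            return build_network([], vertices=["l1"])
        return build_network([("rho", f"l{i}") for i in range(1, n + 1)])
    if not 2 <= k <= n:
        raise BadK(f"k must be 0 or in 2..{n}, got {k}")
    arcs = [("rho", f"l{i}") for i in range(1, n + 1)]
    arcs += [
        (f"l{i}", f"x{j}")
        for i in range(1, k + 1)
        for j in range(1, k + 1)
    ]
    return build_network(arcs)


# --- brute-force oracles ------------------------------------------------------
def oracle_tree_based(n: Network) -> bool:
    """Exhaust every choice of one in-arc per non-root vertex; N is
    tree-based iff some choice keeps an out-arc at every inner vertex."""
    nonroot = sorted(n.vertices - {n.root})
    parent_lists = [sorted(n.parents(v)) for v in nonroot]
    total = 1
    for pl in parent_lists:
        total *= len(pl)
        if total > 2_000_000:
            raise InstanceTooLarge("too many parent-choice functions")
    inner = n.inner_vertices
    for choice in itertools.product(*parent_lists):
        kept_out = set(choice)
        if inner <= kept_out:
            return True
    return False


def oracle_lca(n: Network, a: Iterable[str]) -> Set[VertexId]:
    """LCA(A) by scanning all vertices for common ancestors and filtering to
    the ancestor-minimal ones."""
    query = frozenset(str(x) for x in a)
    common = [v for v in n.vertices if query <= n.cluster(v)]
    return {
        v for v in common
        if not any(w != v and n.descends(w, v) for w in common)
    }


# --- exhaustive enumeration of small quasi-binary level-1 networks ------------
def _set_partitions(items: List[str]) -> Iterator[List[List[str]]]:
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def _ordered_partitions(items: List[str], k: int) -> Iterator[List[List[str]]]:
    for part in _set_partitions(items):
        if len(part) == k:
            for perm in itertools.permutations(part):
                yield [list(p) for p in perm]


def _terms(labels: FrozenSet[str], memo: Dict) -> List[tuple]:
    """All structural terms of phylogenetic quasi-binary level-1 networks on
    the given leaf set.  Terms: ('leaf', x) | ('tree', children) |
    ('block', arm1, arm2, hybrid_child) where each arm is a tuple of
    interior-vertex pendant-lists."""
    if labels in memo:
        return memo[labels]
    items = sorted(labels)
    if len(items) == 1:
        memo[labels] = [("leaf", items[0])]
        return memo[labels]
    out: List[tuple] = []
    # ordinary tree vertex over a set partition into >= 2 parts
    for part in _set_partitions(items):
        if len(part) < 2:
            continue
        options = [_terms(frozenset(p), memo) for p in part]
        for combo in itertools.product(*options):
            out.append(("tree", tuple(sorted(combo))))
    # cycle block: hybrid child gets S_h, the rest is strung along two arms
    for r in range(1, len(items)):
        for sh in itertools.combinations(items, r):
            rest = [x for x in items if x not in sh]
            if not rest:
                continue
            h_opts = _terms(frozenset(sh), memo)
            for m in range(1, len(rest) + 1):
                for bundles in _ordered_partitions(rest, m):
                    interior_opts = []
                    for bundle in bundles:
                        vertex_opts = []
                        for pend_part in _set_partitions(sorted(bundle)):
                            sub_opts = [
                                _terms(frozenset(p), memo) for p in pend_part
                            ]
                            for combo in itertools.product(*sub_opts):
                                vertex_opts.append(tuple(sorted(combo)))
                        interior_opts.append(vertex_opts)
                    for interiors in itertools.product(*interior_opts):
                        for a in range(1, m + 1):
                            arm1 = tuple(interiors[:a])
                            arm2 = tuple(interiors[a:])
                            for h_term in h_opts:
                                out.append(("block", arm1, arm2, h_term))
    memo[labels] = out
    return out


def _materialize(term: tuple, counter: itertools.count) -> Tuple[List[Arc], str]:
    kind = term[0]
    if kind == "leaf":
        return [], term[1]
    if kind == "tree":
        arcs: List[Arc] = []
        root = f"i{next(counter)}"
        for child in term[1]:
            sub, sub_root = _materialize(child, counter)
            arcs += sub
            arcs.append((root, sub_root))
        return arcs, root
    _, arm1, arm2, h_term = term
    arcs = []
    root = f"i{next(counter)}"
    h = f"g{next(counter)}"
    for arm in (arm1, arm2):
        prev = root
        for pendants in arm:
            w = f"i{next(counter)}"
            arcs.append((prev, w))
            for p in pendants:
                sub, sub_root = _materialize(p, counter)
                arcs += sub
                arcs.append((w, sub_root))
            prev = w
        arcs.append((prev, h))
    sub, sub_root = _materialize(h_term, counter)
    arcs += sub
    arcs.append((h, sub_root))
    return arcs, root


_CONSTRAINT_CHECKS = {
    "binary": lambda n: n.is_binary(),
    "separated": lambda n: n.is_separated(),
    "shortcut_free": lambda n: n.is_shortcut_free(),
    "galled_tree": lambda n: n.is_galled_tree(),
    "tree_child": lambda n: n.is_tree_child(),
    "normal": lambda n: n.is_normal(),
    "conventional": lambda n: n.is_conventional(),
    "quasi_binary": lambda n: n.is_quasi_binary(),
    "phylogenetic": lambda n: n.is_phylogenetic(),
    "level1": lambda n: n.level() <= 1,
}


def enumerate_small_networks(
    leaves: Iterable[str],
    constraints: Optional[Mapping[str, bool]] = None,
    max_vertices: Optional[int] = None,
) -> Iterator[Network]:
    """All phylogenetic quasi-binary level-1 networks on the given leaf set,
    pairwise non-isomorphic under the leaf-fixing relation, optionally
    filtered by constraint flags and a vertex budget.

    The enumeration is constructive (tree vertices / cycle blocks with
    pendant subnetworks) and therefore restricted to this universe; it is
    intended for exhaustive checks of encoding and uniqueness statements on
    very small leaf sets (at most 4 labels).
    """
    labels = frozenset(str(x) for x in leaves)
    if len(labels) > 4:
        raise InstanceTooLarge("enumeration limited to 4 leaves")
    memo: Dict = {}
    nets: List[Network] = []
    by_multiset: Dict[tuple, List[Network]] = {}
    for term in _terms(labels, memo):
        arcs, root = _materialize(term, itertools.count(1))
        if arcs:
            net = build_network(arcs)
        else:
            net = build_network([], vertices=[root])
        if max_vertices is not None and len(net) > max_vertices:
            continue
        key = cluster_multiset(net).canonical()
        bucket = by_multiset.setdefault(key, [])
        if any(isomorphic(net, other) for other in bucket):
            continue
        bucket.append(net)
        nets.append(net)
    for net in nets:
        if constraints and not all(
            _CONSTRAINT_CHECKS[k](net) == v for k, v in constraints.items()
        ):
            continue
        yield net
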