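"""Readers and writers.

Three plain-text formats:

* edge list: one ``parent<TAB>child`` per line, ``#`` comments; leaf labels
  default to the vertex id and can be overridden with
  ``label<TAB>vertex<TAB>name`` lines.
* extended Newick: the common dialect where hybrid vertices carry ``#H<k>``
  tags, the first occurrence of a tag carries the subtree and later
  occurrences are leaf-like references.
* clustering systems: JSON ``{"X": [...], "clusters": [[...], ...]}`` or a
  plain-text file with one comma-separated cluster per line.  Singletons and
  X are auto-added on read unless ``strict=True``.
"""
from __future__ import annotations

import json
import os
from typing import Dict, List, Optional, Set, Tuple, Union

from .clusters import ClusteringSystem, _key
from .errors import ParseError, UnmatchedHybridTag
from .network import Network, VertexId, build_network

PathLike = Union[str, os.PathLike]


# --- edge lists ---------------------------------------------------------------
def read_edgelist(path: PathLike) -> Network:
    arcs: List[Tuple[str, str]] = []
    labels: Dict[str, str] = {}
    singletons: List[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            if parts[0] == "label":
                if len(parts) != 3:
                    raise ParseError("label lines need 'label\\tvertex\\tname'",
                                     line=lineno)
                labels[parts[1]] = parts[2]
            elif parts[0] == "vertex" and len(parts) == 2:
                singletons.append(parts[1])
            elif len(parts) == 2:
                arcs.append((parts[0], parts[1]))
            else:
                raise ParseError(f"expected 'parent\\tchild', got {line!r}",
                                 line=lineno)
    leaves = {v for _, v in arcs} - {u for u, _ in arcs}
    leaves |= set(singletons) - {u for u, _ in arcs} - {v for _, v in arcs}
    full_labels = {v: labels.get(v, v) for v in leaves}
    return build_network(arcs, full_labels, vertices=singletons)


def write_edgelist(n: Network, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if not n.arcs:  # single-vertex network
            fh.write(f"vertex\t{n.root}\n")
        for u, v in sorted(n.arcs):
            fh.write(f"{u}\t{v}\n")
        for v in sorted(n.leaves):
            if n.leaf_labels[v] != v:
                fh.write(f"label\t{v}\t{n.leaf_labels[v]}\n")


# --- extended Newick ----------------------------------------------------------
def write_enewick(n: Network) -> str:
    """Serialize to extended Newick.  Hybrid vertices receive #H<k> tags in
    lexicographic order of their ids; the first traversal occurrence carries
    the subtree.  Children are ordered by (smallest leaf label in the
    cluster, vertex id) for determinism."""
    tags = {h: f"#H{i}" for i, h in enumerate(sorted(n.hybrids), start=1)}
    written: Set[VertexId] = set()

    def render(v: VertexId) -> str:
        if v in tags and v in written:
            return tags[v]
        written.add(v)
        tag = tags.get(v, "")
        if n.is_leaf(v):
            return n.leaf_labels[v] + tag
        kids = sorted(
            n.children(v), key=lambda c: (min(n.cluster(c)), c)
        )
        return "(" + ",".join(render(c) for c in kids) + ")" + tag

    return render(n.root) + ";"


class _Token:
    __slots__ = ("kind", "value")

    def __init__(self, kind: str, value: str = ""):
        self.kind = kind
        self.value = value


def _tokenize(text: str) -> List[_Token]:
    tokens: List[_Token] = []
    i = 0
    text = text.strip()
    while i < len(text):
        ch = text[i]
        if ch in "(),;":
            tokens.append(_Token(ch))
            i += 1
        elif ch.isspace():
            i += 1
        else:
            j = i
            while j < len(text) and text[j] not in "(),;" and not text[j].isspace():
                j += 1
            tokens.append(_Token("name", text[i:j]))
            i = j
    return tokens


def _split_name(name: str) -> Tuple[Optional[str], Optional[str]]:
    """'x#H1' -> ('x', 'H1'); '#H1' -> (None, 'H1'); 'x' -> ('x', None)."""
    if "#" in name:
        label, tag = name.split("#", 1)
        if not tag.startswith("H") or not tag[1:].isdigit():
            raise ParseError(f"malformed hybrid tag in {name!r}")
        return (label or None), tag
    return (name or None), None


def read_enewick(text: str) -> Network:
    """Parse extended Newick into a network.  Subtrees that share a hybrid
    tag are merged into a single vertex; each tag must occur at least twice
    (a tag used once has no second parent and raises UnmatchedHybridTag)."""
    tokens = _tokenize(text)
    if not tokens or tokens[-1].kind != ";":
        raise ParseError("expected a ';'-terminated Newick string")
    pos = 0
    counter = [0]
    arcs: List[Tuple[str, str]] = []
    node_label: Dict[str, Optional[str]] = {}
    tag_nodes: Dict[str, List[str]] = {}

    def fresh() -> str:
        counter[0] += 1
        return f"_n{counter[0]}"

    def parse_subtree() -> str:
        nonlocal pos
        vid = fresh()
        if tokens[pos].kind == "(":
            pos += 1
            while True:
                child = parse_subtree()
                arcs.append((vid, child))
                if tokens[pos].kind == ",":
                    pos += 1
                    continue
                if tokens[pos].kind == ")":
                    pos += 1
                    break
                raise ParseError("expected ',' or ')' in Newick string")
        label, tag = None, None
        if pos < len(tokens) and tokens[pos].kind == "name":
            label, tag = _split_name(tokens[pos].value)
            pos += 1
        node_label[vid] = label
        if tag is not None:
            tag_nodes.setdefault(tag, []).append(vid)
        return vid

    root = parse_subtree()
    if tokens[pos].kind != ";":
        raise ParseError("trailing content before ';'")

    # merge vertices that share a hybrid tag
    merge: Dict[str, str] = {}
    for tag, nodes in tag_nodes.items():
        if len(nodes) < 2:
            raise UnmatchedHybridTag(
                f"hybrid tag #{tag} occurs only once"
            )
        canon = nodes[0]
        for v in nodes[1:]:
            merge[v] = canon
            if node_label.get(v) and not node_label.get(canon):
                node_label[canon] = node_label[v]

    def m(v: str) -> str:
        return merge.get(v, v)

    merged_arcs = {(m(u), m(v)) for u, v in arcs}
    vertices = {m(v) for v in node_label}
    children = {u for u, _ in merged_arcs}
    leaves = vertices - children
    labels = {v: (node_label.get(v) or v) for v in leaves}
    return build_network(merged_arcs, labels, vertices=vertices)


# --- clustering systems -------------------------------------------------------
def read_clustering_system(path: PathLike, strict: bool = False) -> ClusteringSystem:
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if text.lstrip().startswith("{"):
        data = json.loads(text)
        ground = data["X"]
        clusters = [frozenset(map(str, c)) for c in data["clusters"]]
    else:
        clusters = []
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                clusters.append(frozenset(p.strip() for p in line.split(",")))
        ground = sorted(set().union(*clusters)) if clusters else []
    if strict:
        return ClusteringSystem(ground, clusters)
    return ClusteringSystem.complete(ground, clusters)


def write_clustering_system(cs: ClusteringSystem, path: PathLike) -> None:
    data = {
        "X": sorted(cs.X),
        "clusters": [list(_key(c)) for c in cs],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=1)
        fh.write("\n")


def write_network(n: Network, path: PathLike) -> None:
    """Dispatch on extension: .enwk/.newick -> extended Newick, else edge list."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in {".enwk", ".nwk", ".newick"}:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(write_enewick(n) + "\n")
    else:
        write_edgelist(n, path)


def read_network(path: PathLike) -> Network:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in {".enwk", ".nwk", ".newick"}:
        with open(path, "r", encoding="utf-8") as fh:
            return read_enewick(fh.read())
    return read_edgelist(path)
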