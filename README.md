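# phyclus

Rooted phylogenetic networks and their **hardwired clustering systems**: a
calculus connecting network structure with set systems, for people who work
on reticulate evolution (hybridization, horizontal transfer) and need to
reason about what a network's clusters can and cannot tell them.

## The science in brief

A rooted network `N` on a taxon set `X` is a DAG with a unique root; the
*cluster* of a vertex `v` is `C(v) = {x ∈ X : x ⪯ v}`, and the family
`𝒞_N = {C(v)}` is the network's clustering system — always containing `X`
and every singleton.  Trees are exactly the networks whose systems are
hierarchies; beyond trees the correspondence between networks and systems
becomes many-to-many, and this package implements the structure theory that
organizes it:

* **Structural classes** of networks: phylogenetic, separated, binary,
  quasi-binary, conventional, shortcut-free, tree-child, normal, tree-based
  (decided by a bipartite matching on *omnians* — inner vertices all of
  whose children are hybrids), galled trees, level-k (at most k hybrids per
  block besides the block's maximum).
* **Set-system properties**: closedness under intersection, pre-binary /
  binary, weak hierarchies, property **(L)** (`C₁∩C₂ = C₁∩C₃` whenever `C₁`
  overlaps both), **(N3O)** (no three pairwise overlapping clusters),
  paired hierarchies, **(2-Inc)**, pre-pyramidality (interval representable).
* **Least common ancestors** in DAGs: the set `LCA(A)` of ⪯-minimal common
  ancestors, the cluster-lca property (CL), lca-networks (`|LCA(A)| = 1`
  for all `A`), strong lca-networks, and path-cluster-comparability (PCC):
  `u, v` are ⪯-comparable **iff** `C(u)`, `C(v)` are nested.
* **Canonical constructions**: the Hasse diagram `ℌ[𝒞]` of a clustering
  system is the unique *regular* network with clusters `𝒞`; expanding its
  hybrid vertices yields the unique *cluster network* (semi-regular,
  separated, phylogenetic).  `regularize` reduces any PCC network to
  `ℌ[𝒞_N]` by exhausting shortcut removal and outdegree-1 contraction.
* **Level-1 theory**: `𝒞` is the clustering system of a level-1 network
  **iff** it is closed and satisfies (L); adding (N3O) characterizes galled
  trees, adding (2-Inc) binary level-1 networks.  A system is *compatible*
  with a level-1 network (`𝒞 ⊆ 𝒞_N`) iff it satisfies (L) alone; the
  witness is the cluster network of the intersection closure `𝓘(𝒞)`,
  optionally refined to binary via caterpillar resolution.
* **Encoding results**: semi-regular networks, and phylogenetic quasi-binary
  level-1 networks, are determined up to leaf-fixing isomorphism by their
  cluster **multisets** `ℳ_N`; the witnessing bijection `φ_PCC` maps
  equal-cluster chains positionally.

## Worked example

The ten-cluster system
`𝒞 = {{x},{y},{z},{v},{x,y},{x,z},{x,v},{y,z},{y,v},{x,y,z,v}}`
is closed but violates (L).  Its cluster network exists, is semi-regular —
and is *not* tree-based:

```python
>>> import phyclus as pc
>>> cs12 = pc.fixtures()["F_CS12"]
>>> net = pc.cluster_network_of(cs12)
>>> len(net), len(net.hybrids), len(net.omnians)
(14, 4, 5)
>>> net.is_tree_based()
False
>>> pc.check_l1_compatibility(cs12).compatible
False
```

The 14 vertices are the 10 clusters plus one expansion vertex per hybrid;
the five omnians compete for only four hybrid children, so no spanning tree
keeps them all internal — the network cannot be drawn as a tree with added
linking arcs.  Compatibility with a level-1 network fails because (L) fails.

A compatible system, by contrast, gets a witness built for it:

```python
>>> cs = pc.ClusteringSystem("xyz", [{"x"},{"y"},{"z"},{"x","y"},{"y","z"},{"x","y","z"}])
>>> res = pc.check_l1_compatibility(cs)
>>> res.compatible, res.network.is_galled_tree(), res.network.level()
(True, True, 1)
```

## Command line

```bash
phyclus classify net.el               # full flag record as JSON
phyclus hasse cs.json -o net.el       # unique regular network
phyclus cluster-network cs.json -o net.enwk
phyclus l1-compat cs.json --binary    # exit 0/1 with a JSON report
phyclus gen level1 --n 8 --blocks 2 --seed 42 -o net.enwk
phyclus fixtures --name F_CS12 -o cs.json
```

Networks are read and written as plain edge lists or extended Newick with
`#H` hybrid tags; clustering systems as JSON (`{"X": [...], "clusters":
[[...], ...]}`) or one comma-separated cluster per line.

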