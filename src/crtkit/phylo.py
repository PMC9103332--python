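"""Neighbor-joining trees with column-bootstrap support.

Implements the Saitou–Nei agglomeration on Poisson-corrected distance
matrices, nonparametric bootstrap over alignment columns with supports
mapped onto the original tree's internal edges, outgroup rooting, collapsing
of weakly supported edges into polytomies, Robinson–Foulds comparison, and
Newick serialization with supports written as internal-node labels.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .aligndist import DistanceMatrix, Msa, msa_to_distances


@dataclass
class Node:
    """One tree node; ``length`` is the edge to the parent (root: 0)."""

    name: Optional[str] = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)
    support: Optional[float] = None
    raw_length: Optional[float] = None  # pre-clamping NJ estimate

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class Tree:
    root: Node

    @property
    def taxa(self) -> frozenset[str]:
        return self.root.leaf_names()

    def copy(self) -> "Tree":
        return Tree(copy.deepcopy(self.root))

    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining; returns an unrooted tree.

    At each step the pair minimizing Q(i,j) = (n-2) d(i,j) - R_i - R_j is
    joined (ties broken by the smallest (row, column) index pair in the
    current matrix).  Negative branch-length estimates are clamped to zero
    with the deficit moved to the sibling edge; the raw estimate is kept in
    ``Node.raw_length``.  The final three lineages are attached to an
    unresolved root by the three-point formulas.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("distance matrix contains non-finite entries")
    d = dm.d.copy()
    nodes: list[Node] = [Node(name=t) for t in dm.taxa]

    def set_lengths(a: Node, la: float, b: Node, lb: float) -> None:
        a.raw_length, b.raw_length = la, lb
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        a.length, b.length = max(la, 0.0), max(lb, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        new = Node(children=[nodes[i], nodes[j]])
        set_lengths(nodes[i], li, nodes[j], lj)
        du = np.array([(d[i, k] + d[j, k] - d[i, j]) / 2.0 for k in range(m)])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], du[keep]])
        d = np.hstack([d, np.append(du[keep], 0.0).reshape(-1, 1)])
        nodes = [nodes[k] for k in keep] + [new]

    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    for node, ln in zip(
        (a, b, c),
        ((dab + dac - dbc) / 2.0, (dab + dbc - dac) / 2.0, (dac + dbc - dab) / 2.0),
    ):
        node.raw_length = ln
        node.length = max(ln, 0.0)
    return Tree(Node(children=[a, b, c]))


# ---------------------------------------------------------------------------
# Bipartitions and Robinson–Foulds


def bipartitions(tree: Tree) -> dict[frozenset[str], Node]:
    """Non-trivial splits of the tree, canonicalized to the side excluding a
    fixed reference taxon (the lexicographically smallest leaf label)."""
    all_taxa = tree.taxa
    ref = min(all_taxa)
    out: dict[frozenset[str], Node] = {}
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf:
            continue
        clade = node.leaf_names()
        if len(clade) < 2 or len(all_taxa) - len(clade) < 2:
            continue
        key = clade if ref not in clade else all_taxa - clade
        out[key] = node
    return out


def compare_topologies(t1: Tree, t2: Tree) -> int:
    """Robinson–Foulds distance: size of the symmetric difference of the two
    trees' non-trivial bipartition sets."""
    if t1.taxa != t2.taxa:
        raise ValueError("trees have different leaf sets")
    b1, b2 = set(bipartitions(t1)), set(bipartitions(t2))
    return len(b1 ^ b2)


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(
    msa: Msa,
    n_reps: int = 1000,
    seed: int = 0,
    gap_mode: str = "complete",
    retry_cap: int = 100,
) -> Tree:
    """NJ tree from the full alignment, with column-bootstrap edge supports.

    Each replicate ``r`` resamples columns with replacement using an RNG
    stream derived deterministically from ``(seed, r)``, rebuilds distances
    and the NJ tree, and the support of each internal edge of the original
    tree is the percentage of replicates containing the same bipartition.
    A replicate whose resample retains no columns (possible under complete
    deletion) is redrawn, up to ``retry_cap`` attempts.
    """
    original = neighbor_joining(msa_to_distances(msa, gap_mode=gap_mode))
    splits = bipartitions(original)
    counts = {key: 0 for key in splits}
    ncol = msa.n_columns
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        for attempt in range(retry_cap):
            idx = rng.integers(0, ncol, size=ncol)
            try:
                dm = msa_to_distances(msa.subsample_columns(idx), gap_mode=gap_mode)
                break
            except ValueError:
                continue
        else:
            raise RuntimeError(
                f"replicate {r}: no usable resample in {retry_cap} attempts"
            )
        rep_splits = set(bipartitions(neighbor_joining(dm)))
        for key in counts:
            if key in rep_splits:
                counts[key] += 1
    for key, node in splits.items():
        node.support = 100.0 * counts[key] / n_reps
    return original


def majority_consensus(msa: Msa, n_reps: int, seed: int,
                       gap_mode: str = "complete") -> Tree:
    """Majority-rule consensus of bootstrap replicate trees (via dendropy)."""
    import dendropy

    ncol = msa.n_columns
    newicks = []
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        idx = rng.integers(0, ncol, size=ncol)
        dm = msa_to_distances(msa.subsample_columns(idx), gap_mode=gap_mode)
        newicks.append(to_newick(neighbor_joining(dm)))
    taxa = dendropy.TaxonNamespace()
    trees = dendropy.TreeList(
        [dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=taxa)
         for nwk in newicks]
    )
    cons = trees.consensus(min_freq=0.5, support_as_percentages=True)
    return read_newick(cons.as_string(schema="newick"))


# ---------------------------------------------------------------------------
# Rooting and collapsing


def root_by_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Root on the outgroup's pendant edge (at its midpoint).

    Supports stay attached to the edges they belong to; the root split
    itself carries no support (it is a trivial split of the unrooted tree).
    Re-rooting on the same outgroup is idempotent.
    """
    t = tree.copy()
    path = _path_to_leaf(t.root, outgroup)
    if path is None:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
    leaf = path[-1]
    parent = path[-2] if len(path) >= 2 else None
    if parent is None:
        raise ValueError("cannot root a single-leaf tree")

    # Already rooted on this pendant edge: re-balance the root edge only.
    if parent is t.root and len(t.root.children) == 2:
        other = next(c for c in t.root.children if c is not leaf)
        total = leaf.length + other.length
        leaf.length = other.length = total / 2.0
        return t

    # Reverse the edges on the path root -> ... -> parent.
    edge_len = [n.length for n in path]
    edge_sup = [n.support for n in path]
    for i in range(len(path) - 2, 0, -1):
        upper, lower = path[i - 1], path[i]
        upper.children.remove(lower)
        lower.children.append(upper)
        upper.length = edge_len[i]
        upper.support = edge_sup[i]

    parent.children.remove(leaf)
    pendant = leaf.length
    leaf.length = pendant / 2.0
    parent.length = pendant / 2.0
    parent.support = None
    new_root = Node(children=[leaf, parent])
    _suppress_unary(new_root)
    return Tree(new_root)


def _path_to_leaf(node: Node, name: str) -> Optional[list[Node]]:
    if node.is_leaf:
        return [node] if node.name == name else None
    for c in node.children:
        sub = _path_to_leaf(c, name)
        if sub is not None:
            return [node] + sub
    return None


def _suppress_unary(node: Node) -> None:
    """Merge degree-2 (single-child internal) nodes created by re-rooting."""
    for c in list(node.children):
        _suppress_unary(c)
    for i, c in enumerate(list(node.children)):
        if not c.is_leaf and len(c.children) == 1:
            only = c.children[0]
            only.length += c.length
            if only.support is None:
                only.support = c.support
            node.children[i] = only


def collapse_low_support(tree: Tree, cutoff: float) -> Tree:
    """Contract internal edges with support below ``cutoff`` into polytomies."""
    t = tree.copy()

    def collapse(node: Node) -> None:
        for c in node.children:
            collapse(c)
        merged = []
        for c in node.children:
            if (not c.is_leaf and c.support is not None and c.support < cutoff):
                merged.extend(c.children)
            else:
                merged.append(c)
        node.children = merged

    collapse(t.root)
    return t


# ---------------------------------------------------------------------------
# Tree metrics and generators (used for simulation and testing)


def tree_to_distance_matrix(tree: Tree) -> DistanceMatrix:
    """Additive (patristic) leaf-to-leaf distances along the tree."""
    taxa = sorted(tree.taxa)
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    d = np.zeros((n, n))

    def below(node: Node) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}
        maps = [
            {k: v + c.length for k, v in below(c).items()} for c in node.children
        ]
        for a in range(len(maps)):
            for b in range(a + 1, len(maps)):
                for la, da in maps[a].items():
                    for lb, db in maps[b].items():
                        d[index[la], index[lb]] = d[index[lb], index[la]] = da + db
        out = {}
        for m in maps:
            out.update(m)
        return out

    below(tree.root)
    return DistanceMatrix(taxa, d)


def random_tree(
    n_leaves: int,
    rng: np.random.Generator,
    min_branch: float = 0.02,
    max_branch: float = 0.3,
    prefix: str = "t",
) -> Tree:
    """Random unrooted binary topology with uniform branch lengths.

    Grown by random sequential addition: starting from the 3-leaf star, each
    new leaf subdivides a uniformly chosen edge.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")

    def blen() -> float:
        return float(rng.uniform(min_branch, max_branch))

    root = Node(children=[Node(name=f"{prefix}1", length=blen()),
                          Node(name=f"{prefix}2", length=blen()),
                          Node(name=f"{prefix}3", length=blen())])
    for k in range(4, n_leaves + 1):
        edges = [(p, c) for p in root.walk() for c in p.children]
        parent, child = edges[rng.integers(0, len(edges))]
        mid = Node(length=child.length / 2.0)
        child.length /= 2.0
        parent.children[parent.children.index(child)] = mid
        mid.children = [child, Node(name=f"{prefix}{k}", length=blen())]
    return Tree(root)


# ---------------------------------------------------------------------------
# Newick I/O


def _fmt_support(s: float) -> str:
    return f"{s:.0f}" if abs(s - round(s)) < 1e-9 else f"{s:.1f}"


def to_newick(tree: Tree, supports: bool = True, precision: int = 6) -> str:
    """Newick string; bootstrap supports are written as internal-node labels."""

    def render(node: Node, top: bool) -> str:
        if node.is_leaf:
            body = node.name
        else:
            inner = ",".join(render(c, False) for c in node.children)
            label = ""
            if supports and node.support is not None:
                label = _fmt_support(node.support)
            body = f"({inner}){label}"
        if top:
            return body
        return f"{body}:{node.length:.{precision}f}"

    return render(tree.root, True) + ";"


def read_newick(text: str) -> Tree:
    """Parse Newick via dendropy; numeric internal labels become supports."""
    import dendropy

    dtree = dendropy.Tree.get(data=text, schema="newick",
                              suppress_internal_node_taxa=True)

    def convert(dnode) -> Node:
        node = Node(length=float(dnode.edge.length or 0.0))
        if dnode.is_leaf():
            node.name = dnode.taxon.label if dnode.taxon else dnode.label
        else:
            node.children = [convert(c) for c in dnode.child_nodes()]
            if dnode.label is not None:
                try:
                    node.support = float(dnode.label)
                except ValueError:
                    node.name = dnode.label
        return node

    return Tree(convert(dtree.seed_node))


def support_table(tree: Tree) -> str:
    """TSV of internal-edge bipartitions and their supports."""
    lines = ["clade\tsupport"]
    for key, node in sorted(bipartitions(tree).items(), key=lambda kv: sorted(kv[0])):
        sup = "" if node.support is None else _fmt_support(node.support)
        lines.append(",".join(sorted(key)) + "\t" + sup)
    return "\n".join(lines) + "\n"
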