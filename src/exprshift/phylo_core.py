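"""Rooted phylogenetic trees: Newick I/O, traversals, clade queries, pruning,
Brownian-motion covariance, and a simple mean-path-length ultrametric utility.

The tree is the coordinate system for the whole pipeline: branch lengths are
expected substitutions per site on sequence trees, arbitrary time units on
chronograms, and re-fitted expression distances on expression trees.  A branch
is always identified by its *child* node, so "the branch of node v" means the
edge from v's parent into v.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "CladeSpec",
    "parse_newick",
    "write_newick",
    "read_clade_specs",
    "tree_covariance",
    "clade_branches",
    "prune_to_tips",
    "make_ultrametric_mpl",
]


class TreeError(ValueError):
    """Raised for malformed or inconsistent trees."""


@dataclass
class PhyloTree:
    """Rooted tree stored as parent-pointer arrays in preorder.

    Node 0 is the root; every node's parent precedes it, so a plain index loop
    is a preorder traversal and a reversed loop is a postorder traversal.

    Parameters
    ----------
    parent : (n_nodes,) int array, ``parent[0] == -1``.
    lengths : (n_nodes,) float array of branch lengths into each node
        (``lengths[0]`` is ignored and kept at 0).
    names : unique node names; tips keep their labels, internal nodes get
        stable auto-names (``N1``, ``N2``, ...) when the source had none.
    """

    parent: np.ndarray
    lengths: np.ndarray
    names: list[str]
    _children: list[list[int]] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        self.lengths = np.asarray(self.lengths, dtype=float)
        n = len(self.parent)
        if len(self.lengths) != n or len(self.names) != n:
            raise TreeError("parent/lengths/names size mismatch")
        if n == 0 or self.parent[0] != -1:
            raise TreeError("node 0 must be the root (parent -1)")
        if np.sum(self.parent == -1) != 1:
            raise TreeError("exactly one root required")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise TreeError("nodes must be in preorder (parent before child)")
        if np.any(self.lengths[1:] < 0):
            raise TreeError("negative branch length")
        if len(set(self.names)) != n:
            dups = sorted({x for x in self.names if self.names.count(x) > 1})
            raise TreeError(f"duplicate node names: {dups}")
        self.lengths = self.lengths.copy()
        self.lengths[0] = 0.0

    # -- basic structure -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def children(self) -> list[list[int]]:
        if self._children is None:
            ch = [[] for _ in range(self.n_nodes)]
            for v in range(1, self.n_nodes):
                ch[self.parent[v]].append(v)
            self._children = ch
        return self._children

    @property
    def is_tip(self) -> np.ndarray:
        counts = np.zeros(self.n_nodes, dtype=int)
        np.add.at(counts, self.parent[1:], 1)
        return counts == 0

    @property
    def tip_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    @property
    def tip_labels(self) -> list[str]:
        return [self.names[i] for i in self.tip_indices]

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no node named {name!r}") from None

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    # -- metrics ---------------------------------------------------------
    def depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        d = np.zeros(self.n_nodes)
        for v in range(1, self.n_nodes):
            d[v] = d[self.parent[v]] + self.lengths[v]
        return d

    def total_length(self) -> float:
        return float(self.lengths[1:].sum())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        td = self.depths()[self.tip_indices]
        return bool(np.ptp(td) <= rtol * max(td.max(), 1e-300))

    def subtree(self, node: int) -> np.ndarray:
        """All node indices in the subtree rooted at ``node`` (inclusive)."""
        mask = np.zeros(self.n_nodes, dtype=bool)
        mask[node] = True
        for v in range(node + 1, self.n_nodes):
            if mask[self.parent[v]]:
                mask[v] = True
        return np.flatnonzero(mask)

    def tips_below(self, node: int) -> list[str]:
        sub = self.subtree(node)
        tip = self.is_tip
        return [self.names[v] for v in sub if tip[v]]

    def mrca(self, labels) -> int:
        """Most recent common ancestor of the named tips (or nodes)."""
        idx = [self.index(x) for x in labels]
        if not idx:
            raise TreeError("mrca of an empty set")
        # mark ancestor paths; the deepest node on all paths is the MRCA
        counts = np.zeros(self.n_nodes, dtype=int)
        for v in idx:
            while v != -1:
                counts[v] += 1
                v = self.parent[v]
        common = np.flatnonzero(counts == len(idx))
        return int(common.max())  # preorder => max index is deepest

    def path_length(self, a: str, b: str) -> float:
        d = self.depths()
        i, j = self.index(a), self.index(b)
        m = self.mrca([a, b])
        return float(d[i] + d[j] - 2 * d[m])

    def with_lengths(self, new_lengths) -> "PhyloTree":
        return PhyloTree(self.parent.copy(), np.asarray(new_lengths, float),
                         list(self.names))

    def copy(self) -> "PhyloTree":
        return self.with_lengths(self.lengths)


@dataclass(frozen=True)
class CladeSpec:
    """A named clade defined as the MRCA of a set of tips."""

    name: str
    mrca_tips: tuple

    def __post_init__(self):
        if len(self.mrca_tips) < 2:
            raise ValueError("CladeSpec needs >= 2 tips")


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    parent, lengths, names = [], [], []
    index = {}
    auto = 0
    seen = set()
    for node in dtree.preorder_node_iter():
        i = len(parent)
        index[node] = i
        parent.append(index[node.parent_node] if node.parent_node else -1)
        el = node.edge.length
        if el is None:
            if node.parent_node is not None:
                warnings.warn("branch length missing in Newick; defaulting to 0")
            el = 0.0
        lengths.append(float(el))
        if node.taxon is not None:
            nm = node.taxon.label
        elif node.label:
            nm = node.label
        else:
            nm = None
        if nm is None or nm in seen:
            auto += 1
            nm = f"N{auto}"
            while nm in seen:
                auto += 1
                nm = f"N{auto}"
        seen.add(nm)
        names.append(nm)
    return PhyloTree(np.array(parent), np.array(lengths), names)


def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted Newick string into a :class:`PhyloTree`.

    Tip labels must be unique; missing branch lengths default to 0 with a
    warning; internal labels are preserved when present.
    """
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dups = sorted({x for x in labels if labels.count(x) > 1})
        raise TreeError(f"duplicate tip labels: {dups}")
    return _from_dendropy(dtree)


def write_newick(tree: PhyloTree, internal_labels: bool = True) -> str:
    """Serialize to a rooted Newick string (children in stored order)."""

    def render(v: int) -> str:
        ch = tree.children[v]
        nm = tree.names[v]
        if not ch:
            core = nm
        else:
            inner = ",".join(render(c) for c in ch)
            core = f"({inner})" + (nm if internal_labels else "")
        if v == 0:
            return core + ":0"
        return f"{core}:{tree.lengths[v]:.12g}"

    return render(0) + ";"


def read_clade_specs(path) -> list[CladeSpec]:
    """Read clade specs from TSV with columns: name, comma-separated tips."""
    specs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, tips = line.split("\t")[:2]
            specs.append(CladeSpec(name, tuple(t.strip() for t in tips.split(","))))
    return specs


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def tree_covariance(tree: PhyloTree) -> tuple[np.ndarray, list[str]]:
    """Unit-rate Brownian-motion covariance among tips.

    ``C[i, j]`` is the root-to-MRCA path length shared by tips i and j (their
    shared evolutionary history); the diagonal holds root-to-tip depths.
    Computed by accumulating each branch's length over all tip pairs whose
    lineages both pass through it.
    """
    tips = tree.tip_indices
    pos = {v: k for k, v in enumerate(tips)}
    n = len(tips)
    C = np.zeros((n, n))
    below = [None] * tree.n_nodes
    tipmask = tree.is_tip
    for v in range(tree.n_nodes - 1, 0, -1):  # postorder
        if tipmask[v]:
            below[v] = [pos[v]]
        else:
            acc = []
            for c in tree.children[v]:
                acc.extend(below[c])
            below[v] = acc
        idx = np.array(below[v])
        C[np.ix_(idx, idx)] += tree.lengths[v]
    return C, [tree.names[v] for v in tips]


def clade_branches(tree: PhyloTree, clade: CladeSpec,
                   include_stem: bool = False) -> list[str]:
    """Branch set (child-node names) of the clade's MRCA subtree.

    If the named tips span the whole tree the "clade" is the full branch set;
    a warning is emitted because the stem is then undefined.
    """
    m = tree.mrca(clade.mrca_tips)
    sub = tree.subtree(m)
    out = [tree.names[v] for v in sub if v != m]
    if m == 0:
        warnings.warn(f"clade {clade.name!r} spans the root; returning all branches")
        return out
    if include_stem:
        out.append(tree.names[m])
    return out


def prune_to_tips(tree: PhyloTree, keep) -> PhyloTree:
    """Induced tree on a subset of tips.

    Unbranched internal nodes are suppressed with branch lengths summed, so
    all pairwise tip path lengths are preserved exactly.  Surviving nodes keep
    their names (a suppressed chain keeps the name of its deepest survivor's
    parent-side node is dropped entirely).
    """
    keep = set(keep)
    labels = set(tree.tip_labels)
    if not keep <= labels:
        raise TreeError(f"unknown tips: {sorted(keep - labels)}")
    if len(keep) < 2:
        raise TreeError("need at least 2 tips to prune to")

    n = tree.n_nodes
    tipmask = tree.is_tip
    kept_desc = np.zeros(n, dtype=int)  # number of children subtrees w/ kept tips
    retain = np.zeros(n, dtype=bool)
    for v in range(n - 1, -1, -1):
        if tipmask[v]:
            retain[v] = tree.names[v] in keep
        else:
            k = sum(retain[c] for c in tree.children[v])
            kept_desc[v] = k
            retain[v] = k > 0

    # new root = MRCA of kept tips: deepest retained node with >=2 kept children
    new_root = 0
    v = 0
    while not tipmask[v] and kept_desc[v] == 1:
        v = next(c for c in tree.children[v] if retain[c])
    new_root = v

    parent, lengths, names = [-1], [0.0], [tree.names[new_root]]
    index = {new_root: 0}

    def add(v: int, new_parent: int, acc_len: float):
        ch = [c for c in tree.children[v] if retain[c]]
        if not tipmask[v] and len(ch) == 1 and v != new_root:
            # suppress unary node: fold its branch into the child's
            add(ch[0], new_parent, acc_len + tree.lengths[ch[0]])
            return
        if v not in index:
            i = len(parent)
            index[v] = i
            parent.append(index[new_parent])
            lengths.append(acc_len)
            names.append(tree.names[v])
        for c in ch:
            add(c, v, tree.lengths[c])

    for c in tree.children[new_root]:
        if retain[c]:
            add(c, new_root, tree.lengths[c])

    # remap parent refs: during recursion new_parent may itself be suppressed;
    # handled because suppressed nodes never enter `index` and we always pass
    # the nearest retained ancestor as new_parent.
    return PhyloTree(np.array(parent), np.array(lengths), names)


def make_ultrametric_mpl(tree: PhyloTree) -> PhyloTree:
    """Mean-path-length smoothing to an ultrametric tree.

    Each internal node's age is set to the mean path length to its descendant
    tips; ages are then made monotone top-down (a child older than its parent
    is clamped, zeroing that branch).  The result has every root-to-tip depth
    equal to the original mean tip depth and unchanged topology.  This is a
    deliberately naive smoothing utility, not a penalized-likelihood or other
    rate-model dating method; supply a real chronogram when one exists.
    """
    d = tree.depths()
    tips = tree.tip_indices
    if np.all(d[tips] <= 0):
        raise TreeError("zero-depth tree cannot be made ultrametric")
    n = tree.n_nodes
    tipmask = tree.is_tip
    # postorder: mean path length from node down to its tips
    age = np.zeros(n)
    ntips = np.zeros(n, dtype=int)
    for v in range(n - 1, -1, -1):
        if tipmask[v]:
            ntips[v] = 1
            age[v] = 0.0
        else:
            ch = tree.children[v]
            ntips[v] = sum(ntips[c] for c in ch)
            age[v] = sum(ntips[c] * (tree.lengths[c] + age[c]) for c in ch) / ntips[v]
    # top-down monotone clamp, then branch = parent age - node age
    new = np.zeros(n)
    for v in range(1, n):
        age[v] = min(age[v], age[tree.parent[v]])
        new[v] = age[tree.parent[v]] - age[v]
    return tree.with_lengths(new)
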