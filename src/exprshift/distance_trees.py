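"""Expression distances and distance-based trees.

Distances between species expression profiles are ``1 - rho`` with rho the
Spearman rank correlation over pairwise-complete genes.  Branch lengths of a
fixed (sequence-based) topology are then re-estimated from those distances by
the Fitch-Margoliash weighted least-squares criterion with non-negativity
constraints, and an independent neighbour-joining tree can be built for
display/comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import skbio

from .expression_io import ExpressionMatrix
from .phylo_core import PhyloTree, parse_newick

__all__ = [
    "DistanceMatrix",
    "expression_distance",
    "fitch_margoliash_lengths",
    "neighbor_joining",
    "path_incidence",
]

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    labels: list
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValueError("nonzero diagonal")
        if np.any(self.d < -1e-12):
            raise ValueError("negative distances")
        self.d = np.maximum((self.d + self.d.T) / 2.0, 0.0)
        np.fill_diagonal(self.d, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def loc(self, a, b) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])

    def reorder(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(x) for x in labels]
        return DistanceMatrix(list(labels), self.d[np.ix_(idx, idx)])

    # -- I/O -------------------------------------------------------------
    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, lab in enumerate(self.labels):
                row = " ".join(f"{x:.10g}" for x in self.d[i])
                fh.write(f"{lab}  {row}\n")

    @classmethod
    def from_phylip(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            labels, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:n + 1]])
        return cls(labels, np.array(rows))

    def to_long_tsv(self, path) -> None:
        recs = [(self.labels[i], self.labels[j], self.d[i, j])
                for i in range(self.n) for j in range(i + 1, self.n)]
        pd.DataFrame(recs, columns=["a", "b", "distance"]).to_csv(
            path, sep="\t", index=False)


def expression_distance(X: ExpressionMatrix, min_overlap: int = 50) -> DistanceMatrix:
    """Pairwise expression distances ``1 - Spearman rho`` between columns.

    Correlations use pairwise-complete genes (both species observed); ties get
    average ranks.  Distances lie in [0, 2]: 0 for identical rank profiles,
    2 for a perfect rank reversal.

    Raises if any pair shares fewer than ``min_overlap`` genes or has a
    constant profile on the shared genes (rho undefined).
    """
    cols = X.sample_ids
    n = len(cols)
    if n < 2:
        raise ValueError("need >= 2 species for distances")
    V = X.values
    present = ~np.isnan(V)
    D = np.zeros((n, n))
    complete = present.all(axis=1)
    if complete.all():
        # fast path: rank once per column, then Pearson on ranks
        R = scipy.stats.rankdata(V, axis=0)
        sd = R.std(axis=0)
        if np.any(sd == 0):
            bad = cols[int(np.flatnonzero(sd == 0)[0])]
            raise ValueError(f"constant expression profile for {bad!r}; "
                             "Spearman rho undefined")
        C = np.corrcoef(R, rowvar=False)
        D = 1.0 - C
    else:
        for i in range(n):
            for j in range(i + 1, n):
                sel = present[:, i] & present[:, j]
                if sel.sum() < min_overlap:
                    raise ValueError(
                        f"pair ({cols[i]}, {cols[j]}) shares only "
                        f"{int(sel.sum())} genes (< min_overlap={min_overlap})")
                xi, xj = V[sel, i], V[sel, j]
                if np.all(xi == xi[0]) or np.all(xj == xj[0]):
                    raise ValueError(
                        f"constant profile in pair ({cols[i]}, {cols[j]}); "
                        "Spearman rho undefined")
                ri = scipy.stats.rankdata(xi)
                rj = scipy.stats.rankdata(xj)
                rho = np.corrcoef(ri, rj)[0, 1]
                D[i, j] = D[j, i] = 1.0 - rho
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(cols), D)


def path_incidence(tree: PhyloTree) -> tuple[np.ndarray, list[str], list[tuple]]:
    """Pair x branch incidence matrix of the rooted topology.

    Row (i, j) has a 1 for every branch (child-node column) on the tip path
    i..j — exactly the branches whose subtree contains one of the two tips.
    Returns (A, branch names, tip pairs in (label_i, label_j) order).
    """
    tips = tree.tip_indices
    tipset = {int(t) for t in tips}
    pos = {int(v): k for k, v in enumerate(tips)}
    n = len(tips)
    branches = list(range(1, tree.n_nodes))
    below = {}
    for b in branches:
        below[b] = frozenset(pos[v] for v in tree.subtree(b) if v in tipset)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    A = np.zeros((len(pairs), len(branches)))
    for r, (i, j) in enumerate(pairs):
        for c, b in enumerate(branches):
            A[r, c] = (i in below[b]) != (j in below[b])
    labels = [tree.names[t] for t in tips]
    named_pairs = [(labels[i], labels[j]) for i, j in pairs]
    return A, [tree.names[b] for b in branches], named_pairs


def fitch_margoliash_lengths(topology: PhyloTree, D: DistanceMatrix,
                             power: float = 2.0) -> tuple[PhyloTree, float]:
    """Re-estimate branch lengths of a fixed rooted topology from distances.

    Minimizes the Fitch-Margoliash criterion
    ``sum_{i<j} (d_ij - p_ij(b))^2 / d_ij^power`` over branch lengths b >= 0,
    where p_ij is the tip-to-tip path length.  Solved exactly as non-negative
    weighted least squares on the pair x branch incidence matrix, so the
    non-negativity is a constraint of the fit, not a post-hoc clamp.

    The root position is not identifiable from distances: the two root-adjacent
    branches enter every path together, so their *sum* is fitted and then split
    in proportion to their lengths in ``topology`` (equally if both are zero).

    Returns the topology with new lengths and the achieved criterion value.
    Zero observed distances only affect the weights, where they are replaced
    by ``1e-6 * max(D)``.
    """
    labs = set(D.labels)
    if set(topology.tip_labels) != labs:
        raise ValueError("topology tips != distance labels")
    A, branch_names, pairs = path_incidence(topology)
    Dord = D  # look up by name, order-independent
    d = np.array([Dord.loc(a, b) for a, b in pairs])

    eps = 1e-6 * max(d.max(), 1e-300)
    w = 1.0 / np.maximum(d, eps) ** power
    sw = np.sqrt(w)

    root_children = topology.children[0]
    merged = None
    cols = {nm: k for k, nm in enumerate(branch_names)}
    Afit = A
    fit_names = list(branch_names)
    if len(root_children) == 2:
        c1, c2 = (topology.names[c] for c in root_children)
        k1, k2 = cols[c1], cols[c2]
        if not np.array_equal(A[:, k1], A[:, k2]):  # pragma: no cover
            raise AssertionError("root-adjacent columns expected identical")
        keep = [k for k in range(A.shape[1]) if k != k2]
        Afit = A[:, keep]
        fit_names = [branch_names[k] for k in keep]
        merged = (c1, c2)
    elif len(root_children) > 2:
        warnings.warn("multifurcating root: all root-adjacent branches fitted "
                      "independently; their split is not identifiable")

    if Afit.shape[0] < Afit.shape[1]:
        warnings.warn("fewer tip pairs than branches: branch lengths are not "
                      "fully identifiable")
    b, _ = scipy.optimize.nnls(sw[:, None] * Afit, sw * d)
    lengths = dict(zip(fit_names, b))

    if merged is not None:
        c1, c2 = merged
        tot = lengths[c1]
        l1 = topology.lengths[topology.index(c1)]
        l2 = topology.lengths[topology.index(c2)]
        f = l1 / (l1 + l2) if (l1 + l2) > 0 else 0.5
        lengths[c1] = f * tot
        lengths[c2] = (1 - f) * tot

    new = np.zeros(topology.n_nodes)
    for nm, val in lengths.items():
        new[topology.index(nm)] = val
    fitted = topology.with_lengths(new)
    resid = d - A @ np.array([lengths[nm] for nm in branch_names])
    objective = float(np.sum(w * resid ** 2))
    return fitted, objective


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbour joining, midpoint-rooted for display.

    Negative NJ branch lengths are clamped to zero with a warning (this tree
    is for display/topology comparison only; RRBL uses the constrained
    Fitch-Margoliash fit instead).
    """
    if D.n < 3:
        raise ValueError("neighbor joining needs >= 3 labels")
    dm = skbio.DistanceMatrix(D.d, ids=[str(x) for x in D.labels])
    nj_tree = skbio.tree.nj(dm)
    n_neg = sum(1 for node in nj_tree.traverse(include_self=False)
                if node.length is not None and node.length < 0)
    if n_neg:
        warnings.warn(f"{n_neg} negative NJ branch lengths clamped to 0")
        for node in nj_tree.traverse(include_self=False):
            if node.length is not None and node.length < 0:
                node.length = 0.0
    rooted = nj_tree.root_at_midpoint()
    for node in rooted.traverse(include_self=False):
        if node.length is not None and node.length < 0:  # numerical dust
            node.length = 0.0
    return parse_newick(str(rooted))
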