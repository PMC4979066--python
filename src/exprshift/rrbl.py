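"""Rescaled relative branch lengths (RRBL) and clade sign-enrichment tests.

After re-fitting branch lengths of the sequence topology from expression
distances, the expression tree is rescaled so both trees have the same total
length; each branch then gets a dimensionless scalar contrasting its
expression-based length BL_EXP against its sequence-based length BL_SEQ.
Positive values mark branches whose gene expression diverged faster than
their sequences; enrichment of positive values inside a clade is assessed
with an exact two-sided binomial test on branch signs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .phylo_core import CladeSpec, PhyloTree, clade_branches

__all__ = [
    "rescale_expression_tree",
    "compute_rrbl",
    "clade_sign_enrichment",
    "lineage_rrbl_summary",
    "rrbl_table_to_tsv",
]

_STATISTICS = ("sym_ratio", "log2_ratio", "rel_diff")


def _check_same_topology(a: PhyloTree, b: PhyloTree) -> None:
    if set(a.tip_labels) != set(b.tip_labels):
        raise ValueError("trees have different tip sets")
    bip_a = {frozenset(a.tips_below(v)) for v in range(1, a.n_nodes)}
    bip_b = {frozenset(b.tips_below(v)) for v in range(1, b.n_nodes)}
    if bip_a != bip_b:
        diff = bip_a ^ bip_b
        raise ValueError(
            f"tree topologies differ in {len(diff)} bipartitions: "
            f"{[sorted(s) for s in list(diff)[:4]]}")


def rescale_expression_tree(exp_tree: PhyloTree, seq_tree: PhyloTree) -> PhyloTree:
    """Scale every expression branch so both trees have equal total length.

    The single factor ``s = sum(BL_SEQ) / sum(BL_EXP_raw)`` makes RRBL
    invariant to the overall scale of the expression distance matrix.
    """
    _check_same_topology(exp_tree, seq_tree)
    tot_exp = exp_tree.total_length()
    tot_seq = seq_tree.total_length()
    if tot_exp <= 0:
        raise ValueError("zero total expression tree length; cannot rescale")
    s = tot_seq / tot_exp
    return exp_tree.with_lengths(exp_tree.lengths * s)


def compute_rrbl(exp_tree_rescaled: PhyloTree, seq_tree: PhyloTree,
                 statistic: str = "sym_ratio", eps: float = 1e-12) -> pd.DataFrame:
    """Per-branch RRBL table contrasting expression vs sequence lengths.

    Statistics (all positive when expression divergence is accelerated):

    * ``sym_ratio`` (default): (BL_EXP - BL_SEQ) / (BL_EXP + BL_SEQ), bounded
      in [-1, 1] and antisymmetric under swapping the trees.
    * ``log2_ratio``: log2(BL_EXP / BL_SEQ), epsilon-guarded.
    * ``rel_diff``: (BL_EXP - BL_SEQ) / BL_SEQ, epsilon-guarded.

    Branches where the statistic is undefined (zero denominators) carry
    RRBL = 0 and ``degenerate = True``; they are excluded from sign tests.
    Rows are indexed by child-node name and aligned by node name (the trees
    share their topology, checked up front).
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; "
                         f"choose from {_STATISTICS}")
    _check_same_topology(exp_tree_rescaled, seq_tree)
    tot_e = exp_tree_rescaled.total_length()
    tot_s = seq_tree.total_length()
    if abs(tot_e - tot_s) > 1e-9 * max(tot_s, 1.0):
        raise ValueError("expression tree not rescaled: total lengths differ "
                         f"({tot_e:.6g} vs {tot_s:.6g})")

    rows = []
    guard = eps * max(tot_s, 1.0)
    for v in range(1, seq_tree.n_nodes):
        child = seq_tree.names[v]
        bl_seq = float(seq_tree.lengths[v])
        ve = exp_tree_rescaled.index(child)
        bl_exp = float(exp_tree_rescaled.lengths[ve])
        degenerate = False
        if statistic == "sym_ratio":
            tot = bl_exp + bl_seq
            if tot <= 0:
                val, degenerate = 0.0, True
            else:
                val = (bl_exp - bl_seq) / tot
        elif statistic == "log2_ratio":
            if bl_exp <= 0 or bl_seq <= 0:
                degenerate = bl_exp <= 0 and bl_seq <= 0
                val = 0.0 if degenerate else float(
                    np.log2(max(bl_exp, guard) / max(bl_seq, guard)))
            else:
                val = float(np.log2(bl_exp / bl_seq))
        else:  # rel_diff
            if bl_seq <= 0:
                degenerate = bl_exp <= 0
                val = 0.0 if degenerate else (bl_exp - bl_seq) / guard
            else:
                val = (bl_exp - bl_seq) / bl_seq
        rows.append({
            "child": child,
            "parent": seq_tree.names[seq_tree.parent[v]],
            "bl_seq": bl_seq,
            "bl_exp": bl_exp,
            "rrbl": val,
            "degenerate": degenerate,
        })
    table = pd.DataFrame(rows).set_index("child")
    table.attrs["statistic"] = statistic
    return table


def clade_sign_enrichment(table: pd.DataFrame, branches,
                          p0: float = 0.5,
                          method: str = "minlike") -> dict:
    """Exact two-sided binomial test for an excess of positive RRBL branches.

    ``k`` = branches with RRBL > 0 among the ``n`` non-degenerate, nonzero
    branches of the set.  ``method='minlike'`` sums all outcome probabilities
    no larger than the observed one (R's binom.test convention);
    ``'doubled'`` doubles the smaller tail.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    sub = table.loc[[b for b in branches if b in table.index]]
    if len(sub) < len(list(branches)):
        missing = sorted(set(branches) - set(table.index))
        raise KeyError(f"branches absent from RRBL table: {missing}")
    informative = sub[(~sub["degenerate"]) & (sub["rrbl"] != 0)]
    n = len(informative)
    if n == 0:
        raise ValueError("no informative branches (all RRBL zero/degenerate)")
    k = int((informative["rrbl"] > 0).sum())
    if method == "minlike":
        p = float(scipy.stats.binomtest(k, n, p0, alternative="two-sided").pvalue)
    elif method == "doubled":
        lo = scipy.stats.binom.cdf(k, n, p0)
        hi = scipy.stats.binom.sf(k - 1, n, p0)
        p = float(min(1.0, 2 * min(lo, hi)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"k_positive": k, "n_informative": n, "p0": p0, "p_value": p,
            "method": method}


def lineage_rrbl_summary(table: pd.DataFrame, tree: PhyloTree,
                         clades: list[CladeSpec],
                         include_stem: bool = True) -> pd.DataFrame:
    """Mean/median RRBL and branch counts per lineage plus background.

    Each branch is assigned to the most nested clade containing it; clades
    must be nested or disjoint.  Branches in no clade form the background row.
    """
    sets = {c.name: set(clade_branches(tree, c, include_stem=include_stem))
            for c in clades}
    names = list(sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = sets[a] & sets[b]
            if inter and not (sets[a] <= sets[b] or sets[b] <= sets[a]):
                raise ValueError(f"clades {a!r} and {b!r} overlap without nesting")
    assign = {}
    for br in table.index:
        containing = [nm for nm in names if br in sets[nm]]
        if containing:
            assign[br] = min(containing, key=lambda nm: len(sets[nm]))
        else:
            assign[br] = "background"
    rows = []
    for group in names + ["background"]:
        vals = table.loc[[b for b, g in assign.items() if g == group], "rrbl"]
        if len(vals) == 0:
            continue
        rows.append({"lineage": group, "n_branches": len(vals),
                     "mean_rrbl": float(vals.mean()),
                     "median_rrbl": float(vals.median())})
    return pd.DataFrame(rows).set_index("lineage")


def rrbl_table_to_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="child")
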