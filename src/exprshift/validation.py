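"""Calibration and recovery experiments for the two analyses.

These are the package's statistical self-checks, each a deterministic
function of a seed: Type-I calibration of the BM-null percentile calling and
of the clade sign-enrichment test on neutral data, power/placement of the OU
shift scan on planted optimum shifts, hotspot flagging in a two-hotspot
scenario, and byte-level reproducibility.  Problem sizes are desk-scale
analogues of a full transcriptome study (32 species, a few hundred genes,
100 null replicates) chosen so the whole suite runs in minutes; the methods
note discusses what they do and do not establish.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .bm_null import build_null, call_significant
from .distance_trees import expression_distance, fitch_margoliash_lengths
from .expression_io import ExpressionMatrix, collapse_conspecifics, filter_genes
from .ou_shift import admissible_nodes, lrt_and_fdr, node_shift_outliers, scan_dataset
from .phylo_core import PhyloTree
from .rrbl import clade_sign_enrichment, compute_rrbl, rescale_expression_tree
from .synthetic_data import ScenarioConfig, gen_expression, gen_sequence_tree, gen_yule_tree

# study conditions for the scaled-down experiments
N_SPECIES = 32
N_GENES_NULL = 500
N_REPS = 100
MISSING = 0.1
MIN_SPECIES = 24      # same 75% coverage rule as 30-of-~40+ in a full study
RATE_HET = 0.5


def _species_matrix(tree, cfg, min_species: int | None = None):
    X, smap, truth = gen_expression(cfg, tree)
    Xs = collapse_conspecifics(X, smap)
    Xs = ExpressionMatrix(Xs.data[list(tree.tip_labels)])
    if min_species is None:
        min_species = max(4, int(0.75 * tree.n_tips))
    return filter_genes(Xs, min_species), truth


def _rrbl_table(seq_tree: PhyloTree, Xs: ExpressionMatrix) -> pd.DataFrame:
    D = expression_distance(Xs)
    exp_tree, _ = fitch_margoliash_lengths(seq_tree, D)
    return compute_rrbl(rescale_expression_tree(exp_tree, seq_tree), seq_tree)


def bm_null_calibration(seed: int) -> dict:
    """Fraction of branches called significant when the data ARE neutral.

    BM data for 32 species, 500 genes, 100-replicate null, pooled 2.5/97.5
    calling: the expected fraction is ~5%.  The neutral traits drift along
    the *sequence* tree — the null model's own assumption (under neutrality
    expression divergence accumulates with sequence divergence, not with
    time), so this measures the calling machinery, not model mismatch.
    """
    tree = gen_yule_tree(N_SPECIES, seed=seed, normalize_depth=True)
    seq = gen_sequence_tree(tree, RATE_HET, seed=seed)
    cfg = ScenarioConfig(n_species=N_SPECIES, n_genes=N_GENES_NULL,
                         generator="bm", seed=seed, missing_fraction=MISSING)
    Xs, _ = _species_matrix(seq, cfg)
    table = _rrbl_table(seq, Xs)
    null = build_null(seq, Xs, n_reps=N_REPS, seed=seed + 1)
    called = call_significant(table, null)
    n = int((~called["degenerate"]).sum())
    k = int(called["significant"].sum())
    return {"sig_fraction": k / n, "n_called": k, "n_branches": n,
            "n_genes": Xs.n_genes, "n_reps": null.n_reps}


def _enrichment_clade(seq_tree: PhyloTree, min_tips: int = 5) -> list[str]:
    """Branches of the largest non-root-child clade (stem included)."""
    tips = seq_tree.is_tip
    best, best_n = None, 0
    root_children = set(seq_tree.children[0])
    for v in range(1, seq_tree.n_nodes):
        if v in root_children or tips[v]:
            continue
        sub = seq_tree.subtree(v)
        n = int(tips[sub].sum())
        if n >= min_tips and seq_tree.n_tips - n >= min_tips and n > best_n:
            best, best_n = v, n
    if best is None:
        raise ValueError("no suitable clade on this tree")
    return [seq_tree.names[u] for u in seq_tree.subtree(best)]


def enrichment_fpr(seed: int, n_datasets: int = 20) -> dict:
    """Rejection rate of the clade sign test on neutral (BM) datasets.

    Each replicate dataset gets a fresh tree, a fixed focal clade, and the
    full distance -> FM -> rescale -> RRBL pipeline; at alpha = 0.05 the
    two-sided binomial test should reject rarely.  As in
    :func:`bm_null_calibration`, neutral traits drift along the sequence
    tree.
    """
    rejects = 0
    for d in range(n_datasets):
        s = seed + 101 * d
        tree = gen_yule_tree(N_SPECIES, seed=s, normalize_depth=True)
        seq = gen_sequence_tree(tree, RATE_HET, seed=s)
        cfg = ScenarioConfig(n_species=N_SPECIES, n_genes=N_GENES_NULL,
                             generator="bm", seed=s, missing_fraction=MISSING)
        Xs, _ = _species_matrix(seq, cfg)
        table = _rrbl_table(seq, Xs)
        branches = _enrichment_clade(seq)
        res = clade_sign_enrichment(table, branches)
        rejects += res["p_value"] < 0.05
    return {"reject_rate": rejects / n_datasets, "n_datasets": n_datasets}


def _neighborhood(tree: PhyloTree, node: str) -> set[str]:
    v = tree.index(node)
    out = {node, tree.names[tree.parent[v]]}
    out.update(tree.names[c] for c in tree.children[v])
    return out


def shift_recovery(seed: int, n_shift: int = 100, n_null: int = 100) -> dict:
    """Power and placement of the OU scan on planted shifts.

    100 genes carry an optimum shift of 3 stationary SDs at one node; 100
    genes evolve under single-optimum OU.  After BH-FDR at 0.05 across all
    genes: recovery = fraction of shifted genes called with the best node at
    the planted node or an adjacent one; false-call rate = fraction of OU1
    genes called.
    """
    tree = gen_yule_tree(N_SPECIES, seed=seed, normalize_depth=True)
    cfg2 = ScenarioConfig(n_species=N_SPECIES, n_genes=n_shift,
                          generator="ou2_shift", seed=seed,
                          missing_fraction=MISSING)
    cfg1 = ScenarioConfig(n_species=N_SPECIES, n_genes=n_null,
                          generator="ou1", seed=seed + 7,
                          missing_fraction=MISSING)
    X2, _, truth2 = gen_expression(cfg2, tree)
    X1, _, _ = gen_expression(cfg1, tree)
    planted = truth2["per_gene"]["shift_node"].iloc[0]
    shifted = [f"shift_{g}" for g in X2.gene_ids]
    data = pd.concat([
        X2.data.set_axis(shifted, axis=0),
        X1.data.set_axis([f"null_{g}" for g in X1.gene_ids], axis=0)])
    Xs = filter_genes(ExpressionMatrix(data[list(tree.tip_labels)]),
                      MIN_SPECIES)
    scan = scan_dataset(tree, Xs)
    per_gene, counts = lrt_and_fdr(scan, alpha_fdr=0.05)
    near = _neighborhood(tree, planted)
    sh = per_gene.loc[[g for g in shifted if g in per_gene.index]]
    recovered = (sh["called"] & sh["best_node"].isin(near)).sum()
    nu = per_gene.loc[per_gene.index.str.startswith("null_")]
    return {
        "recovery_rate": float(recovered / n_shift),
        "false_call_rate": float(nu["called"].mean()),
        "planted_node": planted,
        "top_node": counts.idxmax() if len(counts) else None,
        "n_shift_genes": n_shift, "n_null_genes": n_null,
    }


def _two_disjoint_nodes(tree: PhyloTree, min_tips: int = 4) -> tuple[str, str] | None:
    """Two disjoint, non-adjacent, non-root-child admissible nodes."""
    root_children = {tree.names[c] for c in tree.children[0]}
    cands = [n for n in admissible_nodes(tree, 3) if n not in root_children]
    tips = tree.is_tip
    size = {n: int(tips[tree.subtree(tree.index(n))].sum()) for n in cands}
    cands = [n for n in cands if size[n] >= min_tips]
    cands.sort(key=lambda n: -size[n])
    for i, a in enumerate(cands):
        sub_a = set(tree.subtree(tree.index(a)))
        block = sub_a | {tree.parent[tree.index(a)]}
        for b in cands[i + 1:]:
            vb = tree.index(b)
            sub_b = set(tree.subtree(vb))
            if sub_a.isdisjoint(sub_b) and vb not in block and \
                    tree.index(a) != tree.parent[vb]:
                return a, b
    return None


def two_hotspot_outliers(seed: int, n_per_hotspot: int = 60,
                         n_null: int = 80) -> dict:
    """Hotspot flagging: two planted shift nodes must be the only outliers."""
    node_a = node_b = None
    tree = None
    for trial in range(20):
        tree = gen_yule_tree(N_SPECIES, seed=seed + 1000 * trial,
                             normalize_depth=True)
        pair = _two_disjoint_nodes(tree)
        if pair:
            node_a, node_b = pair
            break
    if node_a is None:
        raise RuntimeError("no tree with two disjoint hotspots found")
    frames = []
    for tag, node, n in [("a", node_a, n_per_hotspot),
                         ("b", node_b, n_per_hotspot)]:
        cfg = ScenarioConfig(n_species=N_SPECIES, n_genes=n,
                             generator="ou2_shift", seed=seed + ord(tag),
                             shift_node=node, missing_fraction=MISSING)
        X, _, _ = gen_expression(cfg, tree)
        frames.append(X.data.set_axis([f"{tag}_{g}" for g in X.gene_ids],
                                      axis=0))
    cfg0 = ScenarioConfig(n_species=N_SPECIES, n_genes=n_null,
                          generator="ou1", seed=seed + 99,
                          missing_fraction=MISSING)
    X0, _, _ = gen_expression(cfg0, tree)
    frames.append(X0.data.set_axis([f"n_{g}" for g in X0.gene_ids], axis=0))
    Xs = filter_genes(ExpressionMatrix(pd.concat(frames)[list(tree.tip_labels)]),
                      MIN_SPECIES)
    scan = scan_dataset(tree, Xs)
    per_gene, counts = lrt_and_fdr(scan, alpha_fdr=0.05)
    counts = counts.reindex(admissible_nodes(tree, 3), fill_value=0)
    flagged = node_shift_outliers(counts)
    flagged_set = set(flagged.index[flagged["outlier"]])
    return {"planted": {node_a, node_b}, "flagged": flagged_set,
            "exact_match": flagged_set == {node_a, node_b},
            "n_genes": Xs.n_genes}


def determinism_check(seed: int) -> dict:
    """Same seed => identical simulated bytes and identical null values."""
    import hashlib

    from .workflow import run_simulate
    import tempfile
    from pathlib import Path

    digests = []
    for _ in range(2):
        with tempfile.TemporaryDirectory() as d:
            run_simulate(ScenarioConfig(n_species=12, n_genes=40, seed=seed), d)
            h = hashlib.sha256()
            for f in ["species_tree.nwk", "sequence_tree.nwk",
                      "expression.tsv", "sample_map.tsv"]:
                h.update((Path(d) / f).read_bytes())
            digests.append(h.hexdigest())
    tree = gen_yule_tree(12, seed=seed, normalize_depth=True)
    seq = gen_sequence_tree(tree, RATE_HET, seed=seed)
    Xs, _ = _species_matrix(tree, ScenarioConfig(
        n_species=12, n_genes=60, generator="bm", seed=seed,
        missing_fraction=0.05))
    n1 = build_null(seq, Xs, n_reps=5, seed=seed, min_overlap=30)
    n2 = build_null(seq, Xs, n_reps=5, seed=seed, min_overlap=30)
    null_identical = bool(np.array_equal(n1.per_branch.to_numpy(),
                                         n2.per_branch.to_numpy()))
    return {"files_identical": digests[0] == digests[1],
            "null_identical": null_identical}
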