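"""Brownian-motion null model for RRBL significance.

For each gene the BM rate and root state are estimated from the observed
species values; neutral expression datasets are then simulated along the
sequence tree (with the empirical per-gene missingness reapplied), the whole
distance -> Fitch-Margoliash -> rescale -> RRBL pipeline is rerun on every
replicate, and the pooled replicate RRBL values form the null distribution
against which observed branches are called significant (outside the
2.5th/97.5th percentiles by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance_trees import expression_distance, fitch_margoliash_lengths
from .expression_io import ExpressionMatrix
from .phylo_core import PhyloTree, prune_to_tips, tree_covariance
from .rrbl import compute_rrbl, rescale_expression_tree

__all__ = [
    "BMParams",
    "NullDistribution",
    "estimate_bm",
    "estimate_bm_matrix",
    "simulate_bm_dataset",
    "build_null",
    "call_significant",
]

log = logging.getLogger(__name__)


@dataclass
class BMParams:
    """Per-gene Brownian-motion parameters on the analysis scale."""

    gene_id: str
    mu: float       # root state (GLS estimate)
    sigma2: float   # drift rate per unit branch length, >= 0
    n_species: int

    def __post_init__(self):
        if not np.isfinite(self.mu) or not np.isfinite(self.sigma2):
            raise ValueError(f"non-finite BM parameters for {self.gene_id}")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")


@dataclass
class NullDistribution:
    """RRBL values from BM-simulated replicates.

    ``per_branch`` is a branches x replicates DataFrame (index = child-node
    names); ``pooled`` flattens it, matching the summarize-across-branches
    convention of the percentile calling.
    """

    per_branch: pd.DataFrame
    seed: int
    statistic: str
    dropped_replicates: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_reps(self) -> int:
        return self.per_branch.shape[1]

    @property
    def pooled(self) -> np.ndarray:
        return self.per_branch.to_numpy().ravel()

    def to_tsv(self, path) -> None:
        long = self.per_branch.reset_index().melt(
            id_vars="child", var_name="replicate", value_name="rrbl")
        long.to_csv(path, sep="\t", index=False)


def _gls_bm(C: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """GLS root state and ML (divide-by-n) BM rate given unit-rate covariance."""
    n = len(x)
    L = np.linalg.cholesky(C)
    ones = np.ones(n)
    a = np.linalg.solve(L, x)
    b = np.linalg.solve(L, ones)
    mu = float(b @ a / (b @ b))
    r = a - mu * b
    sigma2 = float(r @ r / n)
    return mu, sigma2


def estimate_bm(tree: PhyloTree, x: pd.Series, gene_id: str = "gene") -> BMParams:
    """Estimate BM root state and rate for one gene.

    ``x`` is indexed by species; missing species (NaN) are dropped and the
    tree pruned accordingly.  The root state is the generalized-least-squares
    estimate under the BM covariance, the rate the ML estimate (divide by n).
    """
    obs = x.dropna()
    if len(obs) < 3:
        raise ValueError(f"{gene_id}: need >= 3 species with data")
    sub = prune_to_tips(tree, list(obs.index)) if len(obs) < tree.n_tips else tree
    C, labels = tree_covariance(sub)
    v = obs.loc[labels].to_numpy(dtype=float)
    try:
        mu, sigma2 = _gls_bm(C, v)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{gene_id}: singular BM covariance "
                         "(zero-depth duplicate tips?)") from exc
    return BMParams(gene_id, mu, sigma2, len(obs))


def estimate_bm_matrix(tree: PhyloTree, X: ExpressionMatrix) -> pd.DataFrame:
    """Vectorized :func:`estimate_bm` over all genes.

    Genes sharing a missingness pattern share one pruned covariance factor.
    Returns a DataFrame (index = gene) with mu, sigma2, n_species.
    """
    df = X.data
    species = list(df.columns)
    present = df.notna().to_numpy()
    V = df.to_numpy(dtype=float)
    out = pd.DataFrame(index=df.index, columns=["mu", "sigma2", "n_species"],
                       dtype=float)
    patterns: dict[bytes, list[int]] = {}
    for g in range(len(df)):
        patterns.setdefault(present[g].tobytes(), []).append(g)
    full = tree_covariance(tree) if tree.n_tips == len(species) else None
    for key, genes in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        kept = [species[i] for i in range(len(species)) if mask[i]]
        if len(kept) < 3:
            raise ValueError(f"gene {df.index[genes[0]]!r}: fewer than 3 species")
        if len(kept) == tree.n_tips and full is not None:
            C, labels = full
        else:
            C, labels = tree_covariance(prune_to_tips(tree, kept))
        L = np.linalg.cholesky(C)
        col = [species.index(lab) for lab in labels]
        ones = np.ones(len(labels))
        b = np.linalg.solve(L, ones)
        btb = b @ b
        Xg = V[np.ix_(genes, col)]
        A = np.linalg.solve(L, Xg.T)          # (n_sp, n_genes)
        mu = b @ A / btb
        R = A - np.outer(b, mu)
        sigma2 = (R * R).sum(axis=0) / len(labels)
        out.iloc[genes, 0] = mu
        out.iloc[genes, 1] = sigma2
        out.iloc[genes, 2] = len(labels)
    out["n_species"] = out["n_species"].astype(int)
    return out


def simulate_bm_dataset(tree: PhyloTree, params: pd.DataFrame,
                        missing_mask: pd.DataFrame | None,
                        rng: np.random.Generator) -> ExpressionMatrix:
    """Simulate one neutral expression dataset along the tree.

    Every gene starts at its root state mu and gains independent
    Normal(0, sigma2 * branch_length) increments along each branch; the
    supplied per-gene missingness mask (genes x species, True = missing) is
    reapplied so the null mirrors the data's missingness structure.

    Simulated values are raw BM trait values and may be negative; they feed
    the rank-based distance step, which only uses their order.
    """
    if np.any(tree.lengths[1:] < 0):  # PhyloTree already enforces this
        raise ValueError("negative branch length")
    genes = list(params.index)
    sigma = np.sqrt(params["sigma2"].to_numpy(dtype=float))
    n_nodes = tree.n_nodes
    vals = np.empty((len(genes), n_nodes))
    vals[:, 0] = params["mu"].to_numpy(dtype=float)
    z = rng.standard_normal((len(genes), n_nodes - 1))
    for v in range(1, n_nodes):
        bl = tree.lengths[v]
        vals[:, v] = vals[:, tree.parent[v]] + sigma * np.sqrt(bl) * z[:, v - 1]
    tips = tree.tip_indices
    labels = [tree.names[t] for t in tips]
    df = pd.DataFrame(vals[:, tips], index=genes, columns=labels)
    if missing_mask is not None:
        mask = missing_mask.loc[genes, labels].to_numpy(dtype=bool)
        df = df.mask(mask)
    # shift per gene so values are non-negative (rank-invariant, keeps the
    # ExpressionMatrix non-negativity contract)
    mins = df.min(axis=1)
    df = df.sub(mins.clip(upper=0.0), axis=0)
    return ExpressionMatrix(df)


def _rrbl_replicate(seq_tree: PhyloTree, Xsim: ExpressionMatrix,
                    statistic: str, min_overlap: int) -> pd.Series:
    D = expression_distance(Xsim, min_overlap=min_overlap)
    exp_tree, _ = fitch_margoliash_lengths(seq_tree, D)
    exp_resc = rescale_expression_tree(exp_tree, seq_tree)
    table = compute_rrbl(exp_resc, seq_tree, statistic=statistic)
    return table["rrbl"]


def build_null(seq_tree: PhyloTree, X: ExpressionMatrix,
               n_reps: int = 100, seed: int = 0,
               statistic: str = "sym_ratio",
               min_overlap: int = 50,
               max_dropped_frac: float = 0.10) -> NullDistribution:
    """Build the BM null RRBL distribution for an observed dataset.

    Per replicate: simulate every gene under its empirically estimated BM
    parameters, rerun distance -> Fitch-Margoliash -> rescale -> RRBL, and
    collect the per-branch values.  Replicates are seeded independently from
    (seed, replicate index), so results are reproducible and adding
    replicates never reshuffles earlier ones.  A replicate whose pipeline
    fails (e.g. a degenerate distance matrix) is dropped with a warning;
    more than ``max_dropped_frac`` dropped is an error.
    """
    if X.n_genes == 0:
        raise ValueError("empty expression matrix")
    params = estimate_bm_matrix(seq_tree, X)
    mask = pd.DataFrame(X.missing_mask, index=X.gene_ids, columns=X.sample_ids)
    cols = {}
    dropped = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        Xsim = simulate_bm_dataset(seq_tree, params, mask, rng)
        try:
            cols[rep] = _rrbl_replicate(seq_tree, Xsim, statistic, min_overlap)
        except ValueError as exc:
            dropped += 1
            warnings.warn(f"null replicate {rep} dropped: {exc}")
    if n_reps and dropped / n_reps > max_dropped_frac:
        raise RuntimeError(f"{dropped}/{n_reps} null replicates failed")
    per_branch = pd.DataFrame(cols)
    per_branch.index.name = "child"
    log.info("BM null: %d replicates x %d branches (dropped %d)",
             per_branch.shape[1], per_branch.shape[0], dropped)
    return NullDistribution(per_branch, seed=seed, statistic=statistic,
                            dropped_replicates=dropped,
                            meta={"n_genes": X.n_genes})


def call_significant(table: pd.DataFrame, null: NullDistribution,
                     lo: float = 2.5, hi: float = 97.5,
                     mode: str = "pooled") -> pd.DataFrame:
    """Annotate the RRBL table with null percentile bounds and significance.

    ``pooled`` (default) pools null values across branches and replicates, as
    in summarizing RRBL values across branches of the simulated datasets;
    ``per_branch`` uses each branch's own replicate distribution (requires
    >= 20 replicates).  Percentiles use linear interpolation.  A branch is
    significant when its observed RRBL falls outside [null_lo, null_hi];
    degenerate branches are never called.
    """
    if null.per_branch.size == 0:
        raise ValueError("empty null distribution")
    out = table.copy()
    if mode == "pooled":
        qlo, qhi = np.percentile(null.pooled, [lo, hi])
        out["null_lo"] = qlo
        out["null_hi"] = qhi
    elif mode == "per_branch":
        if null.n_reps < 20:
            raise ValueError("per_branch percentiles need >= 20 replicates")
        qs = null.per_branch.reindex(out.index)
        if qs.isna().any().any():
            raise ValueError("null distribution missing branches")
        out["null_lo"] = np.percentile(qs.to_numpy(), lo, axis=1)
        out["null_hi"] = np.percentile(qs.to_numpy(), hi, axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out["significant"] = ((out["rrbl"] < out["null_lo"]) |
                          (out["rrbl"] > out["null_hi"])) & ~out["degenerate"]
    return out
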