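"""Ornstein-Uhlenbeck optimum-shift detection on gene expression.

Per gene, a single-optimum OU model (OU1) is compared against two-regime
models (OU2) that shift the expression optimum at one candidate node: the
derived regime is the branch subtending the focal node plus its whole
subtree.  Following the Hansen formulation, the root state equals the
ancestral-regime optimum; alpha (selection strength) and sigma^2 (drift) are
shared between regimes, so OU1 is nested in every OU2 with one extra free
parameter and the likelihood-ratio statistic is tested against chi^2 with
1 df.  Candidate nodes must leave at least ``min_species`` tips in both
regimes after per-gene pruning.  Gene-wise p-values are Benjamini-Hochberg
corrected; per-node counts of called shifts reveal hotspots, flagged as
Tukey outliers of the count distribution.

The likelihood for an ultrametric tree of depth T uses tip expectations
``E[X_i] = sum_r theta_r W_ir`` with exponentially discounted regime weights
and covariance ``V_ij = sigma^2/(2 alpha) e^{-2 alpha (T - t_ij)}
(1 - e^{-2 alpha t_ij})`` where t_ij is the depth of the tips' MRCA;
``alpha = 0`` dispatches to the Brownian-motion limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .expression_io import ExpressionMatrix
from .phylo_core import PhyloTree, prune_to_tips, tree_covariance

__all__ = [
    "OUParams",
    "RegimePainting",
    "OUSolver",
    "ou_loglik",
    "fit_ou1",
    "fit_ou2",
    "scan_shifts",
    "scan_dataset",
    "lrt_and_fdr",
    "node_shift_outliers",
]

log = logging.getLogger(__name__)

ALPHA_MIN = 1e-6
N_GRID = 21
_LOG2PI = np.log(2 * np.pi)


@dataclass
class OUParams:
    """Fitted OU parameters for one gene (one or two optima)."""

    alpha: float
    sigma2: float
    theta: np.ndarray          # [theta] for OU1, [ancestral, derived] for OU2
    loglik: float
    converged: bool
    n_species: int
    focal_node: str | None = None

    def __post_init__(self):
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if self.alpha < 0 or self.sigma2 < 0:
            raise ValueError("alpha and sigma2 must be >= 0")
        if self.focal_node is not None and len(self.theta) != 2:
            raise ValueError("a two-regime fit needs exactly 2 optima")

    @property
    def stationary_var(self) -> float:
        return self.sigma2 / (2 * self.alpha) if self.alpha > 0 else np.inf


@dataclass
class RegimePainting:
    """Two-regime branch painting induced by one focal node.

    The derived regime is the branch into ``focal_node`` plus its entire
    subtree; everything else (including the root state) is ancestral.
    """

    focal_node: str
    derived_tips: frozenset
    derived_branches: frozenset
    stem_parent_depth: float   # depth at which lineages enter the derived regime

    @classmethod
    def at_node(cls, tree: PhyloTree, focal_node: str,
                min_species: int = 3) -> "RegimePainting":
        v = tree.index(focal_node)
        if v == 0:
            raise ValueError("cannot paint a shift at the root")
        sub = tree.subtree(v)
        tips = tree.is_tip
        derived = frozenset(tree.names[u] for u in sub if tips[u])
        n_anc = tree.n_tips - len(derived)
        if len(derived) < min_species or n_anc < min_species:
            raise ValueError(
                f"painting at {focal_node!r} leaves {len(derived)} derived / "
                f"{n_anc} ancestral tips (< min_species={min_species})")
        depths = tree.depths()
        return cls(focal_node, derived,
                   frozenset(tree.names[u] for u in sub),
                   float(depths[tree.parent[v]]))


class OUSolver:
    """Profiled OU likelihood machinery for one (pruned, ultrametric) tree.

    For fixed alpha the optima are profiled out by GLS and sigma^2 in closed
    form, leaving a 1-D search over alpha.  Cholesky factors of the unit-rate
    covariance are cached per alpha, so a node scan reuses them across
    candidate paintings and across genes sharing a missingness pattern.
    """

    def __init__(self, tree: PhyloTree, ultrametric_rtol: float = 1e-6):
        self.tree = tree
        C0, labels = tree_covariance(tree)
        self.C0 = C0
        self.labels = labels
        depths = np.diag(C0)
        self.T = float(depths.mean())
        dev = float(np.ptp(depths))
        if dev > ultrametric_rtol * max(self.T, 1e-300):
            raise ValueError(
                f"tree is not ultrametric: tip depth range {dev:.3g} exceeds "
                f"tolerance (max deviation {dev:.3g} vs depth {self.T:.3g}); "
                "supply a chronogram or use make_ultrametric_mpl")
        self.n = len(labels)
        self.alpha_max = 50.0 / self.T
        self.grid = np.geomspace(ALPHA_MIN, self.alpha_max, N_GRID)
        self._cache: dict[float, tuple] = {}

    # -- covariance ------------------------------------------------------
    def v0(self, alpha: float) -> np.ndarray:
        """Unit-sigma^2 OU covariance (BM covariance at alpha == 0)."""
        if alpha == 0:
            return self.C0
        T, t = self.T, self.C0
        return np.exp(-2 * alpha * (T - t)) * (1 - np.exp(-2 * alpha * t)) / (2 * alpha)

    def _factor(self, alpha: float):
        key = float(alpha)
        hit = self._cache.get(key)
        if hit is None:
            V0 = self.v0(alpha)
            L = np.linalg.cholesky(V0)
            logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
            b = np.linalg.solve(L, np.ones(self.n))
            hit = (L, logdet, b)
            if len(self._cache) < 4096:
                self._cache[key] = hit
        return hit

    def weights(self, alpha: float, painting: RegimePainting | None) -> np.ndarray:
        """Tip x regime design matrix of exponential regime weights.

        Rows sum to 1; the root's weight e^{-alpha T} accrues to the
        ancestral regime (Hansen root convention).
        """
        if painting is None:
            return np.ones((self.n, 1))
        w_der = np.zeros(self.n)
        in_der = np.array([lab in painting.derived_tips for lab in self.labels])
        # derived episode runs from the focal branch's top to the present
        w_der[in_der] = 1.0 - np.exp(-alpha * (self.T - painting.stem_parent_depth))
        return np.column_stack([1.0 - w_der, w_der])

    # -- likelihoods -----------------------------------------------------
    def loglik(self, x: np.ndarray, alpha: float, sigma2: float,
               theta: np.ndarray, painting: RegimePainting | None) -> float:
        """Exact multivariate-normal log-likelihood at given parameters."""
        theta = np.atleast_1d(theta)
        L, logdet, _ = self._factor(alpha)
        mean = self.weights(alpha, painting) @ theta
        r = np.linalg.solve(L, x - mean)
        n = self.n
        return float(-0.5 * (n * _LOG2PI + n * np.log(sigma2) + logdet
                             + (r @ r) / sigma2))

    def profile(self, x: np.ndarray, alpha: float,
                painting: RegimePainting | None) -> tuple[float, np.ndarray, float]:
        """Profiled log-likelihood over (theta, sigma2) at fixed alpha.

        Returns (loglik, theta_hat, sigma2_hat); GLS for theta, ML
        (divide-by-n) for sigma2.
        """
        L, logdet, b = self._factor(alpha)
        a = np.linalg.solve(L, x)
        if painting is None:
            G = b[:, None]
        else:
            W = self.weights(alpha, painting)
            G = np.column_stack([b - np.linalg.solve(L, W[:, 1]),
                                 np.linalg.solve(L, W[:, 1])])
        theta, *_ = np.linalg.lstsq(G, a, rcond=None)
        r = a - G @ theta
        n = self.n
        rss = float(r @ r)
        if rss <= 0:
            rss = np.finfo(float).tiny
        sigma2 = rss / n
        ll = -0.5 * (n * _LOG2PI + n * np.log(sigma2) + logdet + n)
        return float(ll), theta, float(sigma2)

    def grid_profile(self, x: np.ndarray,
                     painting: RegimePainting | None) -> np.ndarray:
        """Profiled log-likelihood over the standard alpha grid."""
        return np.array([self.profile(x, a, painting)[0] for a in self.grid])

    def fit(self, x: np.ndarray, painting: RegimePainting | None,
            extra_alphas: tuple = ()) -> OUParams:
        """ML fit: grid search over alpha plus bounded local refinement."""
        alphas = list(self.grid) + [a for a in extra_alphas
                                    if ALPHA_MIN <= a <= self.alpha_max]
        lls = [self.profile(x, a, painting)[0] for a in alphas]
        k = int(np.argmax(lls))
        best_alpha, best_ll = alphas[k], lls[k]
        # bracket on the sorted alpha axis, refine on log scale
        srt = np.sort(np.asarray(alphas))
        pos = int(np.searchsorted(srt, best_alpha))
        lo = srt[max(pos - 1, 0)]
        hi = srt[min(pos + 1, len(srt) - 1)]
        converged = True
        if hi > lo:
            res = scipy.optimize.minimize_scalar(
                lambda la: -self.profile(x, float(np.exp(la)), painting)[0],
                bounds=(np.log(lo), np.log(hi)), method="bounded",
                options={"xatol": 1e-4})
            if res.success and -res.fun > best_ll:
                best_alpha, best_ll = float(np.exp(res.x)), float(-res.fun)
            converged = bool(res.success)
        ll, theta, sigma2 = self.profile(x, best_alpha, painting)
        return OUParams(alpha=best_alpha, sigma2=sigma2, theta=theta,
                        loglik=ll, converged=converged, n_species=self.n,
                        focal_node=painting.focal_node if painting else None)


def _as_solver(tree: PhyloTree, x: pd.Series) -> tuple[OUSolver, np.ndarray]:
    obs = x.dropna()
    sub = prune_to_tips(tree, list(obs.index)) if len(obs) < tree.n_tips else tree
    solver = OUSolver(sub)
    return solver, obs.loc[solver.labels].to_numpy(dtype=float)


def ou_loglik(tree: PhyloTree, x: pd.Series, painting: RegimePainting | None,
              alpha: float, sigma2: float, theta) -> float:
    """OU (or BM, at ``alpha == 0``) log-likelihood at explicit parameters.

    ``x`` is indexed by species; the tree must be ultrametric.  With
    ``alpha == 0`` the painting is ignored (regimes are unidentifiable in the
    BM limit) and ``theta`` acts as the root state.
    """
    solver, v = _as_solver(tree, x)
    if alpha == 0:
        theta0 = float(np.atleast_1d(theta)[0])
        return solver.loglik(v, 0.0, sigma2, np.array([theta0]), None)
    return solver.loglik(v, alpha, sigma2, np.atleast_1d(theta), painting)


def fit_ou1(tree: PhyloTree, x: pd.Series) -> OUParams:
    """ML fit of the single-optimum OU model for one gene."""
    obs = x.dropna()
    if len(obs) < 4:
        return OUParams(ALPHA_MIN, 0.0, np.array([float(obs.mean())]),
                        -np.inf, False, len(obs))
    if np.ptp(obs.to_numpy(dtype=float)) == 0:
        return OUParams(ALPHA_MIN, 0.0, np.array([float(obs.iloc[0])]),
                        -np.inf, False, len(obs))
    solver, v = _as_solver(tree, x)
    return solver.fit(v, None)


def fit_ou2(tree: PhyloTree, x: pd.Series, focal_node: str,
            min_species: int = 3, extra_alphas: tuple = ()) -> OUParams:
    """ML fit of the two-regime OU model with a shift at ``focal_node``."""
    solver, v = _as_solver(tree, x)
    painting = RegimePainting.at_node(solver.tree, focal_node, min_species)
    return solver.fit(v, painting, extra_alphas=extra_alphas)


def admissible_nodes(tree: PhyloTree, min_species: int = 3) -> list[str]:
    """Candidate shift nodes: both regimes keep >= min_species tips."""
    tips = tree.is_tip
    out = []
    for v in range(1, tree.n_nodes):
        n_der = int(tips[tree.subtree(v)].sum())
        if n_der >= min_species and tree.n_tips - n_der >= min_species:
            out.append(tree.names[v])
    return out


def scan_shifts(tree: PhyloTree, x: pd.Series, min_species: int = 3,
                _solver: OUSolver | None = None) -> tuple[OUParams, OUParams]:
    """Fit OU1 and the best single-shift OU2 over all admissible nodes.

    The tree is pruned to the gene's observed species first; admissibility
    (>= min_species tips in both regimes) is judged on the pruned tree.  All
    candidates are profiled on the shared alpha grid; the best candidate is
    then refined, with the OU1 alpha-hat added to its candidate set so the
    likelihood-ratio statistic is non-negative by construction.  Grid ties
    break towards the node earliest in preorder.

    Returns (ou1_fit, best ou2_fit).  Raises ``ValueError`` if no node is
    admissible or the gene is degenerate.
    """
    if _solver is None:
        solver, v = _as_solver(tree, x)
    else:
        solver = _solver
        v = x.dropna().loc[solver.labels].to_numpy(dtype=float)
    if len(v) < 4:
        raise ValueError("need >= 4 species with data")
    if np.ptp(v) == 0:
        raise ValueError("constant expression values (degenerate gene)")
    cands = admissible_nodes(solver.tree, min_species)
    if not cands:
        raise ValueError(f"no admissible shift node (min_species={min_species})")
    ou1 = solver.fit(v, None)
    best_name, best_ll = None, -np.inf
    for name in cands:  # preorder by construction -> first wins ties
        painting = RegimePainting.at_node(solver.tree, name, min_species)
        ll = float(np.max(solver.grid_profile(v, painting)))
        if ll > best_ll + 1e-12:
            best_name, best_ll = name, ll
    painting = RegimePainting.at_node(solver.tree, best_name, min_species)
    ou2 = solver.fit(v, painting, extra_alphas=(ou1.alpha,))
    return ou1, ou2


def scan_dataset(tree: PhyloTree, X: ExpressionMatrix,
                 min_species: int = 3) -> pd.DataFrame:
    """Run the per-gene OU1-vs-best-OU2 scan over a species-level matrix.

    Genes sharing a missingness pattern share one solver (and its cached
    covariance factors).  Genes that are degenerate, have no admissible node,
    or fail to converge are reported with a ``status`` reason and excluded
    from testing downstream.
    """
    df = X.data
    species = list(df.columns)
    present = df.notna().to_numpy()
    solvers: dict[bytes, OUSolver | str] = {}
    rows = []
    for g, gene in enumerate(df.index):
        key = present[g].tobytes()
        solver = solvers.get(key)
        if solver is None:
            kept = [species[i] for i in range(len(species)) if present[g, i]]
            if len(kept) < 4:
                solver = "too_few_species"
            else:
                sub = prune_to_tips(tree, kept) if len(kept) < tree.n_tips else tree
                try:
                    solver = OUSolver(sub)
                except ValueError:
                    solver = "non_ultrametric"
            solvers[key] = solver
        if isinstance(solver, str):
            rows.append({"gene": gene, "status": solver})
            continue
        x = df.iloc[g]
        try:
            ou1, ou2 = scan_shifts(tree, x, min_species, _solver=solver)
        except ValueError as exc:
            reason = ("constant_gene" if "constant" in str(exc)
                      else "no_admissible_node" if "admissible" in str(exc)
                      else "too_few_species")
            rows.append({"gene": gene, "status": reason})
            continue
        if not (ou1.converged and ou2.converged):
            rows.append({"gene": gene, "status": "not_converged"})
            continue
        rows.append({
            "gene": gene, "status": "ok", "n_species": ou1.n_species,
            "loglik_ou1": ou1.loglik, "loglik_ou2": ou2.loglik,
            "best_node": ou2.focal_node,
            "n_candidates": len(admissible_nodes(solver.tree, min_species)),
            "alpha": ou2.alpha, "sigma2": ou2.sigma2,
            "theta_anc": ou2.theta[0], "theta_der": ou2.theta[1],
        })
    out = pd.DataFrame(rows).set_index("gene")
    n_ok = int((out["status"] == "ok").sum())
    log.info("OU scan: %d/%d genes fitted (%s)", n_ok, len(out),
             out["status"].value_counts().to_dict())
    return out


def lrt_and_fdr(scan: pd.DataFrame, alpha_fdr: float = 0.05,
                lambda_tol: float = 1e-6,
                correction: str = "none") -> tuple[pd.DataFrame, pd.Series]:
    """Likelihood-ratio tests with Benjamini-Hochberg FDR control.

    ``Lambda = 2 (loglik_OU2 - loglik_OU1)`` is referred to chi^2 with 1 df;
    genes with q < ``alpha_fdr`` are called as preferring a shift and
    aggregated into per-node counts.  Negative Lambda beyond ``lambda_tol``
    (impossible for nested fits) raises.

    The default p-value treats the best-fitting shift node as if it had been
    chosen a priori, which is anti-conservative: taking the maximum over the
    candidate-node scan inflates Lambda well beyond chi^2(1) even when no
    shift exists.  ``correction='candidates'`` Bonferroni-multiplies each
    gene's p-value by its number of admissible candidate nodes, giving a
    conservative scan-aware alternative.
    """
    ok = scan[scan["status"] == "ok"].copy()
    if len(ok) == 0:
        raise ValueError("no successfully fitted genes to test")
    lam = 2.0 * (ok["loglik_ou2"] - ok["loglik_ou1"])
    if (lam < -lambda_tol).any():
        bad = ok.index[lam < -lambda_tol][:5]
        raise AssertionError(f"negative LRT statistic for {list(bad)}")
    ok["lambda"] = lam.clip(lower=0.0)
    ok["p"] = scipy.stats.chi2.sf(ok["lambda"], df=1)
    if correction == "candidates":
        ok["p"] = np.minimum(1.0, ok["p"] * ok["n_candidates"])
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    _, q, _, _ = multipletests(ok["p"], method="fdr_bh")
    ok["q"] = q
    ok["called"] = ok["q"] < alpha_fdr
    counts = (ok.loc[ok["called"], "best_node"].value_counts()
              .rename_axis("node").rename("n_genes_shifted"))
    result = scan.join(ok[["lambda", "p", "q", "called"]])
    result["called"] = result["called"].eq(True)
    return result, counts


def node_shift_outliers(counts: pd.Series) -> pd.DataFrame:
    """Flag hotspot nodes by the Tukey rule on per-node shift counts.

    A node is an outlier when its count exceeds Q3 + 1.5 IQR of the count
    distribution (strictly), so a flat distribution flags nothing.  Needs
    counts for >= 5 nodes (zeros included by the caller where relevant).
    """
    if len(counts) < 5:
        raise ValueError("need counts for >= 5 nodes")
    vals = counts.to_numpy(dtype=float)
    q1, q3 = np.percentile(vals, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    out = pd.DataFrame({"n_genes_shifted": counts.astype(int)})
    out["outlier"] = vals > fence
    out.attrs["fence"] = float(fence)
    return out.sort_values("n_genes_shifted", ascending=False)
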