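"""Independent brute-force oracles for cross-checking the implementation.

Everything here recomputes quantities from first principles by a different
route than the package: path walks instead of subtree accumulation, numerical
integration instead of closed-form OU covariances, generic constrained
optimization instead of NNLS, scipy's multivariate normal instead of
hand-rolled Cholesky algebra.
"""

from __future__ import annotations

import numpy as np
import scipy.integrate
import scipy.optimize
import scipy.stats

from exprshift.phylo_core import PhyloTree


# -- tree geometry by explicit path walks -----------------------------------

def root_path(tree: PhyloTree, node: int) -> list[int]:
    """Nodes from the root down to ``node`` (inclusive)."""
    path = []
    v = node
    while v != -1:
        path.append(v)
        v = tree.parent[v]
    return path[::-1]


def path_length_walk(tree: PhyloTree, a: str, b: str) -> float:
    """Tip-to-tip distance as the symmetric difference of root paths."""
    pa = root_path(tree, tree.index(a))
    pb = root_path(tree, tree.index(b))
    shared = {x for x in pa} & {x for x in pb}
    return float(sum(tree.lengths[v] for v in pa + pb
                     if v not in shared))


def covariance_walk(tree: PhyloTree) -> tuple[np.ndarray, list[str]]:
    """BM covariance as summed branch lengths on intersecting root paths."""
    tips = list(tree.tip_indices)
    n = len(tips)
    C = np.zeros((n, n))
    paths = [root_path(tree, t) for t in tips]
    for i in range(n):
        for j in range(n):
            shared = set(paths[i]) & set(paths[j])
            C[i, j] = sum(tree.lengths[v] for v in shared)
    return C, [tree.names[t] for t in tips]


def path_matrix(tree: PhyloTree) -> dict:
    labs = sorted(tree.tip_labels)
    return {(a, b): path_length_walk(tree, a, b)
            for i, a in enumerate(labs) for b in labs[i + 1:]}


def bipartitions(tree: PhyloTree) -> set:
    """Non-trivial splits as frozensets of tip labels (unrooted sense)."""
    labs = frozenset(tree.tip_labels)
    out = set()
    for v in range(1, tree.n_nodes):
        below = frozenset(tree.tips_below(v))
        if 1 < len(below) < len(labs) - 1:
            out.add(min(below, labs - below, key=sorted))
    return out


def rf_distance(a: PhyloTree, b: PhyloTree) -> int:
    return len(bipartitions(a) ^ bipartitions(b))


# -- Spearman by the rank-difference formula --------------------------------

def spearman_dist_formula(x, y) -> float:
    """1 - rho via 1 - 6*sum(d^2)/(n(n^2-1)); valid without ties."""
    x, y = np.asarray(x), np.asarray(y)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    n = len(x)
    rho = 1 - 6 * np.sum((rx - ry) ** 2) / (n * (n ** 2 - 1))
    return float(1 - rho)


# -- Fitch-Margoliash by generic constrained optimization -------------------

def fm_objective(tree: PhyloTree, lengths: dict, dist: dict,
                 power: float = 2.0, eps_frac: float = 1e-6) -> float:
    """FM criterion for named branch lengths against a distance dict."""
    t = tree.with_lengths(np.array(
        [0.0] + [lengths[tree.names[v]] for v in range(1, tree.n_nodes)]))
    dmax = max(dist.values())
    obj = 0.0
    for (a, b), d in dist.items():
        p = t.path_length(a, b)
        w = 1.0 / max(d, eps_frac * dmax) ** power
        obj += w * (d - p) ** 2
    return obj


def fm_brute(tree: PhyloTree, dist: dict, n_starts: int = 8,
             seed: int = 0) -> tuple[dict, float]:
    """Constrained FM fit by multi-start L-BFGS-B on the branch space.

    The two root-adjacent branches are tied to one variable (their sum) and
    split evenly afterwards; the criterion only sees the sum, so any split
    attains the same objective.
    """
    names = [tree.names[v] for v in range(1, tree.n_nodes)]
    root_children = [tree.names[c] for c in tree.children[0]]
    merged = root_children[1] if len(root_children) == 2 else None
    free = [nm for nm in names if nm != merged]

    def unpack(b):
        lengths = dict(zip(free, b))
        if merged is not None:
            tot = lengths[root_children[0]]
            lengths[root_children[0]] = tot / 2
            lengths[merged] = tot / 2
        return lengths

    rng = np.random.default_rng(seed)
    dmean = np.mean(list(dist.values()))
    best, best_obj = None, np.inf
    for s in range(n_starts):
        x0 = rng.uniform(0, dmean, len(free)) if s else np.full(len(free), dmean / 4)
        res = scipy.optimize.minimize(
            lambda b: fm_objective(tree, unpack(b), dist), x0,
            method="L-BFGS-B", bounds=[(0, None)] * len(free),
            options={"ftol": 1e-14, "gtol": 1e-12, "maxiter": 2000})
        if res.fun < best_obj:
            best, best_obj = unpack(res.x), float(res.fun)
    return best, best_obj


# -- OU mean/covariance from explicit path integrals ------------------------

def ou_mean_cov_quad(tree: PhyloTree, alpha: float, sigma2: float,
                     theta: np.ndarray, derived_tips=frozenset(),
                     shift_depth: float = None):
    """OU tip mean vector and covariance by numerical integration.

    For tip i at depth T_i, the mean integrates the optimum along the
    lineage, discounted at rate alpha:
    ``E_i = theta_anc e^{-a T_i} + int_0^{T_i} a e^{-a (T_i - s)}
    theta(s) ds``; with a single shift, theta(s) jumps to the derived value
    at ``shift_depth`` on derived lineages.  The covariance integrates the
    accumulated noise over the shared history:
    ``V_ij = sigma2 e^{-a (T_i + T_j)} int_0^{t_ij} e^{2 a s} ds``.
    """
    theta = np.atleast_1d(theta)
    tips = list(tree.tip_indices)
    labels = [tree.names[t] for t in tips]
    d = tree.depths()
    n = len(tips)
    mean = np.zeros(n)
    for k, t in enumerate(tips):
        T = d[t]
        if labels[k] in derived_tips:
            def th(s):
                return theta[1] if s >= shift_depth else theta[0]
        else:
            def th(s):
                return theta[0]
        integrand = lambda s: alpha * np.exp(-alpha * (T - s)) * th(s)
        val, _ = scipy.integrate.quad(integrand, 0, T, limit=400,
                                      points=[shift_depth] if shift_depth else None)
        mean[k] = theta[0] * np.exp(-alpha * T) + val
    V = np.zeros((n, n))
    for i, ti in enumerate(tips):
        for j, tj in enumerate(tips):
            pa = set(root_path(tree, ti)) & set(root_path(tree, tj))
            tij = sum(tree.lengths[v] for v in pa)
            f = lambda s: np.exp(2 * alpha * s)
            val, _ = scipy.integrate.quad(f, 0, tij, limit=400)
            V[i, j] = sigma2 * np.exp(-alpha * (d[ti] + d[tj])) * val
    return mean, V, labels


def mvn_loglik(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    return float(scipy.stats.multivariate_normal.logpdf(x, mean=mean, cov=cov,
                                                        allow_singular=False))


# -- exact two-sided binomial by enumeration --------------------------------

def binom_two_sided_minlike(k: int, n: int, p0: float) -> float:
    pmf = scipy.stats.binom.pmf(np.arange(n + 1), n, p0)
    return float(pmf[pmf <= pmf[k] * (1 + 1e-12)].sum())
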