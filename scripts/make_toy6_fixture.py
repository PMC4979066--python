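"""Generate the toy6 fixture bundle, with expected outputs from the oracles.

Run from repo root:  python scripts/make_toy6_fixture.py
"""
import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

REPO = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(REPO / "tests"))
import oracles  # noqa: E402

import exprshift as es  # noqa: E402
from exprshift.expression_io import collapse_conspecifics  # noqa: E402
from exprshift.ou_shift import admissible_nodes, scan_shifts  # noqa: E402
from exprshift.phylo_core import write_newick  # noqa: E402

OUT = REPO / "src/exprshift/fixtures/toy6"
OUT.mkdir(parents=True, exist_ok=True)

SEED = 20
tree = es.gen_yule_tree(6, seed=SEED, normalize_depth=True)
print(write_newick(tree))
print("admissible:", admissible_nodes(tree, 3))
assert admissible_nodes(tree, 3), "need an admissible node; change SEED"
seq_tree = es.gen_sequence_tree(tree, 0.6, seed=SEED)

# species-level traits under BM
cfg = es.ScenarioConfig(n_species=6, n_genes=20, generator="bm", seed=SEED,
                        n_accessions=1, accession_noise_sd=0.0,
                        missing_fraction=0.0)
Xsp, _, truth = es.gen_expression(cfg, tree)
sp_vals = Xsp.data  # 20 x 6, columns are species

# accession-level matrix: S1 gets two noisy accessions, others one
rng = np.random.default_rng(1234)
cols = {}
smap_rows = []
for sp in sp_vals.columns:
    if sp == "S1":
        for a in (1, 2):
            sid = f"S1_a{a}"
            cols[sid] = np.clip(sp_vals[sp] + rng.normal(0, 0.05, len(sp_vals)), 0, None)
            smap_rows.append((sid, sp, "leaf"))
    else:
        cols[sp] = sp_vals[sp]
        smap_rows.append((sp, sp, "leaf"))
acc = pd.DataFrame(cols, index=sp_vals.index)
acc.loc["g5", "S3"] = np.nan  # one missing cell

(OUT / "tree.nwk").write_text(write_newick(tree) + "\n")
(OUT / "seq_tree.nwk").write_text(write_newick(seq_tree) + "\n")
acc.to_csv(OUT / "expression.tsv", sep="\t", index_label="gene_id", na_rep="")
with open(OUT / "sample_map.tsv", "w") as fh:
    fh.write("sample_id\tspecies\ttissue\n")
    for r in smap_rows:
        fh.write("\t".join(r) + "\n")

# ---- expected RRBL via oracles -------------------------------------------
X = es.read_expression(OUT / "expression.tsv")
smap = es.read_sample_map(OUT / "sample_map.tsv")
Xs = collapse_conspecifics(X, smap)
species = list(tree.tip_labels)
V = Xs.data[species]

# pairwise-complete Spearman via scipy
dist = {}
for i, a in enumerate(species):
    for b in species[i + 1:]:
        sub = V[[a, b]].dropna()
        rho = scipy.stats.spearmanr(sub[a], sub[b]).statistic
        dist[(a, b)] = 1 - rho

# brute-force constrained FM, then the package's root-split convention
lengths, obj = oracles.fm_brute(seq_tree, dist, n_starts=10)
rc = [seq_tree.names[c] for c in seq_tree.children[0]]
tot_rc = lengths[rc[0]] + lengths[rc[1]]
l1 = seq_tree.lengths[seq_tree.index(rc[0])]
l2 = seq_tree.lengths[seq_tree.index(rc[1])]
f = l1 / (l1 + l2) if l1 + l2 > 0 else 0.5
lengths[rc[0]], lengths[rc[1]] = f * tot_rc, (1 - f) * tot_rc
print("FM objective (oracle):", obj)

tot_exp = sum(lengths.values())
tot_seq = seq_tree.total_length()
s = tot_seq / tot_exp
rows = []
for v in range(1, seq_tree.n_nodes):
    nm = seq_tree.names[v]
    bl_exp = s * lengths[nm]
    bl_seq = seq_tree.lengths[v]
    rrbl = 0.0 if bl_exp + bl_seq <= 0 else (bl_exp - bl_seq) / (bl_exp + bl_seq)
    rows.append({"child": nm, "parent": seq_tree.names[seq_tree.parent[v]],
                 "bl_seq": bl_seq, "bl_exp": bl_exp, "rrbl": rrbl})
pd.DataFrame(rows).set_index("child").to_csv(OUT / "expected_rrbl.tsv", sep="\t",
                                             float_format="%.12g")

# ---- expected OU scan: package argmax, logliks re-verified by oracle ------
ou_rows = []
for gene in V.index:
    x = V.loc[gene]
    try:
        ou1, ou2 = scan_shifts(tree, x, min_species=3)
    except ValueError as exc:
        print(f"{gene}: skipped ({exc})")
        ou_rows.append({"gene": gene, "best_node": "none",
                        "loglik_ou1": np.nan, "loglik_ou2": np.nan,
                        "lambda": np.nan, "p": np.nan})
        continue
    # oracle recomputation of both logliks at the fitted parameters
    sub_tips = list(x.dropna().index)
    ptree = es.prune_to_tips(tree, sub_tips) if len(sub_tips) < 6 else tree
    m1, V1, labs = oracles.ou_mean_cov_quad(ptree, ou1.alpha, ou1.sigma2,
                                            ou1.theta)
    xv = x.dropna().loc[labs].to_numpy()
    ll1 = oracles.mvn_loglik(xv, m1, V1)
    nd = ptree.index(ou2.focal_node)
    derived = frozenset(ptree.tips_below(nd))
    shift_depth = float(ptree.depths()[ptree.parent[nd]])
    m2, V2, labs2 = oracles.ou_mean_cov_quad(ptree, ou2.alpha, ou2.sigma2,
                                             ou2.theta, derived, shift_depth)
    assert labs2 == labs
    ll2 = oracles.mvn_loglik(xv, m2, V2)
    assert abs(ll1 - ou1.loglik) < 1e-7, (gene, ll1, ou1.loglik)
    assert abs(ll2 - ou2.loglik) < 1e-7, (gene, ll2, ou2.loglik)
    lam = max(0.0, 2 * (ll2 - ll1))
    ou_rows.append({"gene": gene, "best_node": ou2.focal_node,
                    "loglik_ou1": ll1, "loglik_ou2": ll2, "lambda": lam,
                    "p": scipy.stats.chi2.sf(lam, 1)})
pd.DataFrame(ou_rows).set_index("gene").to_csv(OUT / "expected_ou_scan.tsv",
                                               sep="\t", float_format="%.12g")

meta = {f.name: hashlib.sha256(f.read_bytes()).hexdigest()
        for f in sorted(OUT.iterdir()) if f.name != "meta.json"}
(OUT / "meta.json").write_text(json.dumps(meta, indent=2))
print("fixture written:", sorted(p.name for p in OUT.iterdir()))
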