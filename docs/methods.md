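# Methods

## Scope and data model

The package analyses a genes × samples matrix of normalized expression
values on a rooted species phylogeny.  Samples map to species; conspecific
accessions are collapsed to their arithmetic mean on the analysis scale
before any species-level step, and a gene enters an analysis only if it is
observed in at least `min_species` species (default 30, the conventional
coverage rule for multi-species transcriptome ortholog sets; scale it to
~75% of the species count for smaller studies).  Missing cells represent
genes absent from a sample's transcriptome assembly.  The expression scale
is taken as given: Spearman-based steps are invariant to any strictly
monotone per-value transform (asserted by test), but the OU models operate
on the analysis scale, so the optional `log2p1` transform changes OU
results and is off by default.

Trees are rooted; branches are identified by their child node.  Polytomies
are accepted on input, but the OU scan requires well-resolved shift nodes
and the Fitch–Margoliash root handling assumes a bifurcating root.

## RRBL: expression vs sequence divergence per branch

1. **Distances.** `d(i,j) = 1 − ρ` with ρ the Spearman correlation of the
   two species' expression profiles over pairwise-complete genes (average
   ranks for ties; at least `min_overlap = 50` shared genes per pair).
   Range [0, 2].
2. **Branch re-estimation.** With the sequence topology fixed, branch
   lengths are refit to the expression distances by weighted least squares
   with weights `1/d²` and non-negativity *constraints* (non-negative least
   squares on the pair × branch incidence matrix — the constraint shapes
   the optimum, it is not a post-hoc clamp).  The root position is
   unidentifiable from distances: the two root-adjacent branches are fitted
   as their sum and split in proportion to their sequence-tree lengths.
   Zero observed distances affect only the weights, where they are replaced
   by `1e-6 × max(d)`.
3. **Rescaling.** All expression branches are multiplied by
   `Σ BL_SEQ / Σ BL_EXP` so both trees have equal total length; RRBL is
   therefore invariant to the overall scale of the distance matrix.
4. **Statistic.** Default `sym_ratio = (BL_EXP − BL_SEQ)/(BL_EXP + BL_SEQ)`,
   bounded in [−1, 1], antisymmetric under swapping the trees, zero iff the
   branch lengths agree.  `log2_ratio` and `rel_diff` are provided;
   downstream code is statistic-agnostic.  Branches with zero length in
   both trees are recorded as degenerate and excluded from sign tests.

**Null distribution.**  Under the neutral hypothesis, expression divergence
accumulates *with sequence divergence*: per gene, a Brownian-motion root
state (GLS) and rate (ML, divide-by-n) are estimated on the sequence tree
from the observed species values, and whole datasets are re-simulated along
the sequence tree with the empirical per-gene missingness reapplied.  Each
of the (default 100) replicates passes through the full
distance → refit → rescale → RRBL pipeline.  Significance uses the pooled
2.5th/97.5th percentiles of the replicate RRBL values (linear
interpolation); a per-branch mode exists for stricter calling but needs
≥ 20 replicates.  Replicates draw from `SeedSequence([seed, replicate])`
(numpy PCG64), so adding replicates never reshuffles earlier ones and runs
are bit-reproducible.

**Clade enrichment.**  For a branch set (a named clade, stem included), the
count of positive-RRBL branches among nonzero ones is tested against
Binomial(n, 0.5) with the exact minimum-likelihood two-sided convention
(the doubled-tail convention is available).  Two caveats are documented
rather than hidden: branch signs within a clade are not independent (the
refit couples branches through shared tip paths and the global rescaling),
and if expression tracks *time* while the reference tree measures
*substitutions*, the sign test detects that rate-structure mismatch as
"selection".  The calibration experiments therefore simulate the null on
the sequence tree — the null model's own assumption; measured this way the
pooled calling flags ~6% of branches (nominal 5%) and the clade test
rejects in 0–10% of neutral datasets at α = 0.05.

## OU optimum-shift scan

The trait model is the Hansen Ornstein–Uhlenbeck process on an ultrametric
tree: drift rate σ², attraction α toward a regime-dependent optimum θ, root
state equal to the ancestral-regime optimum.  For tip i at depth T, the
expectation is a weighted mixture of regime optima with exponential
weights; for a single shift on the branch into node v (entered at depth
s₀ = depth of v's parent) the derived weight for tips below v is
`1 − e^{−α(T−s₀)}`, and the covariance is
`V_ij = σ²/(2α) · e^{−2α(T−t_ij)} · (1 − e^{−2α t_ij})` with t_ij the MRCA
depth.  α = 0 dispatches to the exact BM likelihood; α → 0⁺ converges to it
(asserted to 1e-3 at α = 1e-6).

**Fitting.**  For fixed α the optima are profiled out by GLS and σ² in
closed form, leaving a 1-D likelihood in α, maximized on a 21-point log
grid over `[1e-6, 50/tree depth]` followed by bounded refinement.  OU2
shares α and σ² between regimes, so OU1 is nested with exactly one extra
parameter.  During a node scan all candidates are profiled on the shared α
grid (Cholesky factors cached per α and per missingness pattern), the best
candidate is refined, and the OU1 α̂ is added to its candidate set — making
the likelihood-ratio statistic non-negative by construction.  Grid ties
break to the node earliest in preorder.  Genes with < 4 species after
pruning, no admissible candidate (≥ 3 species per regime), zero variance,
or non-convergent fits are excluded with a reason code, mirroring the
routine loss of a few hundred genes in genome-wide OU scans.

**Testing.**  Λ = 2(logL_OU2 − logL_OU1) is referred to χ²₁ and gene-wise
p-values are Benjamini–Hochberg corrected (default FDR 0.05).  Shift calls
are aggregated per node; hotspot nodes are Tukey outliers
(count > Q3 + 1.5·IQR, strict) of the per-node count distribution over all
admissible nodes.

**Known limitation — the best-node LRT is anti-conservative.**  Scanning
~20 candidate nodes and testing the maximum as if pre-specified inflates Λ
far beyond χ²₁ (median ≈ 5.2 vs 0.45 under single-optimum data on 32-tip
trees; half the null genes survive BH at 0.05).  Even the fixed-node test
is mildly liberal at n ≈ 32 (≈ 10% at nominal 5%), a finite-sample effect
of profiling α near its boundary.  The default keeps the conventional 1-df
test because shift *placement* — which the planted-shift experiments show
is excellent (≥ 90% of genes at the planted node or a neighbour, hotspots
flagged exactly) — is the scan's purpose; for calibrated *calling*, use
`lrt_and_fdr(correction="candidates")`, which Bonferroni-multiplies each
gene's p-value by its number of admissible candidates and brings null
calls below 10%.  Interpret genome-wide "X% of genes prefer a shift"
figures from the uncorrected test accordingly.

**Ultrametric requirement.**  OU likelihoods require equal root-to-tip
depths (tolerance 1e-6 relative).  `make_ultrametric_mpl` offers naive
mean-path-length smoothing (node age = mean path to descendant tips,
monotone-clamped top-down) for convenience; it is *not* a dating method —
prefer a real chronogram.  Which tree to use is a genuine degree of
freedom: the scan logs it in the run manifest.

## Synthetic data

The generator emulates the processed inputs of a congeneric transcriptome
study.  Species trees are pure-birth (Yule) with an `Exp(nλ)` hang time
after the last split (no zero-length tips) and are rescaled to mean depth
1.  "Sequence" trees multiply each branch by an independent mean-one
lognormal factor (sd 0.5 by default) — a non-clock stand-in for
substitution-rate variation.  Expression: per-gene location μ ~ N(8, 2)
and rate σ² ~ logN(log 0.1, 0.5) give cross-species Spearman correlations
around 0.97, the regime typical of congeners, where `1 − ρ` responds
approximately linearly to divergence; OU scenarios use α = 5 per unit
depth and plant shifts of 3 stationary SDs (√(σ²/2α)) at a chosen node
(default: the largest admissible non-root-child subtree, avoiding the
near-unidentifiable complement pairing of root children).  Accession
values add N(0, 0.05²) measurement noise; cells go missing uniformly at
random (default 10%, resampled so every gene keeps ≥ 4 species); values
are clipped at zero (vanishingly rare under the defaults; counted in the
truth record).  OU regimes start at their optimum, consistent with the
Hansen root convention (a stationary-start switch exists and matters at
small α).  All draws come from numpy PCG64 via named SeedSequence spawns.

What the generator does *not* emulate: assembly-driven (non-random)
missingness, count noise and normalization artifacts, tissue composition
differences, correlated evolution among genes, and within-species
expression variance beyond a single Gaussian accession term.  Passing
calibration and recovery tests on these data therefore demonstrate the
correctness and internal calibration of the machinery under the stated
model, not robustness to those real-data complications.

## Validation experiment sizes

The self-check experiments (`exprshift.validation`, run by
`scripts/acceptance.py` and the acceptance tests) use desk-scale analogues
of a full study: 32 species, 500 neutral genes and 100 null replicates for
RRBL calibration; 20 neutral datasets for the clade-test Type-I rate;
100 shifted + 100 single-optimum genes for scan power; two planted hotspots
(60 genes each) plus 80 background genes for outlier flagging.  The whole
suite completes in about a minute on one CPU.  Oracle equivalence is
checked against independent reconstructions: OU means/covariances by
numerical path integration with scipy quadrature and densities via
`scipy.stats.multivariate_normal`, and the Fitch–Margoliash criterion
against a multi-start bound-constrained optimizer (agreement ≤ 1e-8 and
≤ 1e-6 respectively; observed ~1e-13).

## Numerical conventions

* GLS/ML linear algebra via Cholesky factorization; residual sums guarded
  against exact zeros; `lstsq` for the 2-column OU2 design (robust to the
  near-collinearity of tiny α).
* Percentiles: linear interpolation (numpy default).
* Newick branch lengths serialized at 12 significant digits; round-trips
  preserve topology, labels and lengths to 1e-9.
* Missing branch lengths parse as 0 with a warning; zero-length internal
  branches are retained, not collapsed.
* All warnings are real warnings; all errors name the offending pair,
  branch, gene or sample.
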