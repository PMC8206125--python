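# Methods

This note documents the models, statistics and numerical choices behind
`locusnet`, and what the synthetic cohorts do and do not emulate.

## Preprocessing

Input is a genes × samples matrix of normalized log2 abundances. Filtering
removes genes, then samples, with more than 50% missing entries (iterated to
a fixed point), then zero-variance genes; remaining missing cells are imputed
with the gene mean before modelling. Sample outliers are scored by
standardized sample-network connectivity: the sample–sample Pearson
correlation is mapped to adjacency `((1 + cor)/2)²`, connectivity `k` is the
off-diagonal row sum, and samples with `Z.k < −2.5` are flagged in a single
pass. The −2.5 cut is a convention, not a calibrated error rate: even in a
homogeneous cohort the expected number of flags is about `n·Φ(−2.5) ≈ 0.6%`
of samples, and the empirical rate is 2–3% because the connectivity
distribution is left-skewed (correlations are compressed against 1). The cut
is configurable; outliers are removed before residualization by default.

Covariate correction is per-gene ordinary least squares on an intercept,
centered continuous covariates (age, postmortem interval) and one-hot
categoricals with the reference level dropped (sex, Hardy death
classification — treated as unordered, since the scale is not
interval-valued — and batch). Residuals plus the gene's grand mean are
returned, so the operation is idempotent and residuals are exactly
orthogonal to the design. Rank deficiency is reported with the offending
columns. Because planted covariate effects are linear in the design, OLS
removes them *exactly*: the contaminated cohort residualizes to the same
matrix as the clean cohort. The projection itself costs a small attenuation
of gene–eigengene correlations (order `k/n` for `k` design columns), which
affects clean and contaminated data identically.

## Network model

Co-expression similarity is biweight midcorrelation: observations are
median-centered, weighted by `w = (1 − u²)²·1{|u| < 1}` with
`u = (x − med)/(9·MAD)`, and correlated. Rows with zero MAD fall back to
Pearson weighting with a warning. No outlier-proportion cap is applied by
default (`bicor_max_p_outliers = 1.0`), matching the robust estimator's own
default; a cap is available for heavy-tailed data.

The signed adjacency is `a_ij = ((1 + cor_ij)/2)^β`, so anticorrelated pairs
map near zero rather than to strong edges. β is selected by a
scale-free-topology scan: for each candidate power, connectivities are
binned into ten equal-width bins on `k` (the convention of the standard
fit index), and `log10` mean frequency is regressed on `log10` mean
connectivity; the signed fit index is `−sign(slope)·R²`. The primary rule is
the *lowest* power reaching fit 0.8. Three safeguards make the rule robust
at simulation scale, where the index is noisy:

* a power is only a candidate if its fit is interpretable — slope in
  `(−4, −0.3)` and connectivity spanning ≥ 0.3 decades. Near-constant
  connectivity (low powers on unstructured data) produces arbitrarily steep
  slopes whose R² is meaningless;
* once the fit curve has formed a real plateau (running maximum ≥ 0.5) and
  fallen more than 0.05 below it, later powers are discarded. A re-rise of
  the index at extreme powers reflects a handful of dominant nodes, not
  scale-free topology, and selecting there collapses most of the network
  into the unassigned label;
* if no candidate reaches 0.8, the lowest candidate within 0.02 of the best
  fit is used (parsimony); with no interpretable candidate at all — pure
  noise — the maximum scanned power is used, which maximizes contrast and
  keeps noise unassigned.

Topological overlap is computed with matrix products,
`TOM_ij = (l_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij)` with
`l_ij = Σ_{u≠i,j} a_iu a_uj`; a triple-loop oracle pins the implementation
to 1e-12. Clustering is average linkage on `1 − TOM`.

## Dynamic hybrid tree cut

Branches are grown bottom-up through the merge list. A branch is *viable*
when it has ≥ `min_module_size` (30) leaves, its core scatter (mean of its
lowest `min_module_size − 1` merge heights) is below a ceiling, and the gap
between the current merge height and that core scatter exceeds a floor.
Ceiling and floor interpolate over the (5th-percentile, 99th-percentile)
height range with the deep-split-dependent fractions
(0.64, 0.73, 0.82, 0.91, 0.95) and `(1 − fraction)·3/4` respectively —
deep split 2 by default. When two viable branches meet, both are finalized
as clusters (members that attached above the ceiling are released as
stragglers); otherwise the smaller side is absorbed. Merges above the cut
height (99th percentile) only terminate branches. A PAM-like second phase
assigns each unlabeled gene to the nearest cluster by average dissimilarity
if that beats its average dissimilarity to the remaining background and the
ceiling, optionally restricted to the gene's own below-cut component
(`pam_respects_dendro`, on by default). Genes failing all criteria keep the
reserved unassigned label 0. Labels are integers ordered by decreasing
module size.

On the default synthetic cohort this recovers the planted five-module
partition at mean adjusted Rand index ≈ 0.87 over ten seeds (the residual
loss is background genes that sit, by sampling accident, close to a module
factor), and on pure noise it leaves 100% of genes unassigned across thirty
seeds.

## Eigengenes, merging, meta-modules

A module eigengene is the first right-singular vector of the module's
row-standardized expression (unit norm, sign-flipped so the mean member
correlation is non-negative); variance explained is the leading squared
singular value over the total. kME is the Pearson correlation of every gene
with every eigengene, with two-sided p from
`t = r·sqrt((n−2)/(1−r²))`. Modules whose eigengenes cluster below height
0.2 (average linkage on `1 − cor`) are merged and eigengenes recomputed,
iterating until no pair exceeds r = 0.8 (≤ 10 iterations). Meta-modules are
branches of the eigengene dendrogram below height 0.5 — a configurable
convention, since only the qualitative grouping is meaningful.

## Preservation and quality Z statistics

For a module evaluated in a cohort, four density statistics (mean signed
adjacency, eigengene variance explained, mean sign-aware kME, mean
sign-aware intramodular correlation — signs taken from the reference) and
three connectivity statistics (correlations between cohorts of intramodular
connectivity, kME, and the vectorized correlation matrix) are computed. The
null permutes module assignments over the union of assigned genes (sizes
fixed, background excluded), giving per-statistic
`Z = (obs − mean_perm)/sd_perm`; `z_density` and `z_connectivity` are
medians of their component Zs and `z_summary` their mean. Thresholds: < 2
none, 2–10 moderate (boundaries inclusive — the strict-inequality phrasing
leaves the boundary undefined, so the moderate band is closed), > 10
strong. Modules above 1,000 genes are subsampled once, seeded. Quality
applies the same composite to repeated random half-splits of the reference
cohort (half as reference, half as test; the larger half takes the odd
sample) and averages per-split summaries; the default is 200 splits with 30
permutations per split — a full 200-permutation null inside each of 200
splits would multiply cost 7-fold for no change in the mean.

Two properties of the permutation null are worth knowing. First, in a
purely modular factor model the *connectivity* null is competitive: a random
assigned-gene set keeps its cross-module identity in both cohorts, so its
between-cohort connectivity correlations are high, and planted modules gain
their evidence mostly through the density components. Second, the natural
negative control is scrambling the module *assignments* (random gene sets,
exactly exchangeable with the null: z centers on 0). Scrambling the
expression matrix's gene labels instead leaves the observed modules with
all-positive reference signs while null draws have mixed signs, which in an
all-positive network biases sign-aware density Zs upward by about +1.5 —
a non-exchangeability of that control, not evidence of preservation.

## Prioritization

Interval modules are those harboring ≥ 1 interval gene (unassigned
excluded). Hubs are interval genes with own-module kME > 0.8 and p < 0.05;
interval genes with non-significant kME (p ≥ 0.05) are excluded from
seeding, mirroring peripheral, low-abundance genes. Top neighbors of a seed
are intramodular genes with Spearman ρ ≥ 0.5 (midranks, t-approximation
p < 0.05); the relation is symmetric for co-modular pairs. Overlap of each
neighbor set with each panel set uses the exact upper-tail hypergeometric
test in integer arithmetic up to universes of 2,000 objects and a stable
pmf recurrence beyond (truncation 1e-16); the default universe is the whole
post-filter network. BH correction is applied within the disease family and
the control family separately, since the two tallies answer different
questions. The driver set is the significant seeds plus, per significant
(seed, set) pair, the seed's neighbors inside that set, with provenance.

## DEG validation

Consensus DEGs are genes with p < 0.05 in both input tables and concordant
fold-change direction (direction agreement is the conservative reading of
"consensus" and can be switched off). Genes are mapped through a homology
table reduced to one-to-one pairs (ambiguous rows dropped, counted). Each
of the three target scales — broad (all genes of interval modules),
subnetwork (top neighbors plus seeds), drivers — gets one exact
hypergeometric test against the homology-filtered universe, at nominal
p < 0.05 (no cross-scale correction by default; the scales are nested, not
independent).

## Synthetic cohorts

Gene `i` in module `q` is `x_i = b_i + r_i·ME_q + sqrt(1 − r_i²)·ε_i` with
standard-normal module eigengenes and noise, loadings `r_i ~ U(0.5, 0.9)`
(one gene per module pinned to the upper bound as a planted hub), and a
per-gene baseline `b_i ~ N(7, 2²)` shared across cohorts. The baseline does
not affect any gene-gene correlation (all correlation estimators center per
gene) but gives the sample–sample network the mean structure real
expression data has; without it, sample-outlier detection has nothing to
see. The default design is 2,000 genes in modules of 400/300/200/150/100
plus 850 background genes, 100 reference and 30 test samples, 21 interval
genes placed round-robin across the modules with one in the background —
the qualitative geometry of a cortical network at desk scale. The test
cohort reuses memberships and loadings with freshly drawn eigengenes and
noise. Covariate effects, when enabled, are exactly linear offsets with
per-gene coefficients.

Disease panels draw a chosen fraction of members from a seed's *true*
neighborhood (co-members with `r_seed·r_g ≥ 0.5`, the population top-neighbor
pool) and the rest uniformly; control panels are uniform draws; no panel
contains its seed. The DEG study draws negative-binomial counts for five
samples per group (the usual size of a mouse-model cohort) with dispersion
0.05 (inbred littermates), log2 fold change −1 on interval genes (hemizygous
dosage) and −0.8 on a random 30% of each interval gene's co-members; the
partner effect size was chosen by a design power analysis so that a
five-versus-five comparison detects partners at roughly the same rate as the
dosage effect itself. Two genuinely different tests produce the two DEG
tables: Welch's t on log2(count+1), and a Wald test from a moment-matched
negative-binomial fit referred to a t distribution with 2(n−1) degrees of
freedom (a plain normal reference is anticonservative at n = 5). A
homology table covers a random 95% of genes.

What the generator does *not* emulate: library-size normalization and GC
bias, isoform structure, correlated background genes (background is
independent noise), age- or region-graded expression, and any real disease
biology in the panels. Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes, at the planted effect sizes —
not that those assumptions hold in any particular tissue.

## Problem sizes and determinism

All simulation-based checks run at the desk-scale default (2,000 genes; the
single-block dense implementation comfortably handles ~5,000 genes, and an
18,000-gene cohort needs about 2.7 GB per dense double-precision matrix —
the practical ceiling). The acceptance script uses 10–20 simulation
replicates per quantity and 200 permutations for preservation. Every source
of randomness flows through `numpy.random.default_rng` (PCG64) seeds derived
from one input seed; fixed seed means bit-identical matrices and
byte-identical CLI output tables (floats are written with the `%.10g`
format, tables in deterministic sort order).

## Known limitations

* The fit-index safeguards in power selection are tuned for desk-scale
  cohorts; on very large real cohorts the plain lowest-power rule usually
  suffices and the safeguards are inert.
* The tree-cut is an independent implementation of the dynamic hybrid
  scheme's published structure; it is verified behaviorally (planted
  recovery, noise specificity) rather than leaf-for-leaf against the
  reference implementation, and absorbs a small number of background genes
  per module at low powers.
* The connectivity preservation components carry little signal in a pure
  factor model (see above); real networks, with graded within-module
  topology, give them more work.
* Quality Z uses half-splits; other split ratios are not implemented.
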