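# Methods

This note documents the models, the synthetic cohort, the numerical choices,
and the limits of what the test suite demonstrates.

## Phenotype construction

Counts enter as feature × sample integer matrices (genes, exons, intron
junctions). Features with CPM > 0 in **strictly more than 40%** of samples
are retained. Exon inclusion is the exon-to-gene CPM ratio (missing where the
gene count is zero); intron excision is a junction's count over its cluster
total, where a cluster is all junctions of one gene — a deliberate
simplification of read-level junction clustering, which operates on
alignments this package never sees. Excision ratios sum to one per cluster
and sample by construction.

Ratios below 0.001 are set missing **per entry** (a per-feature reading of
the same rule is possible; the per-entry rule is logged). Remaining values
are log2-transformed and quantile-normalized per feature by mapping ranks
(ties averaged) onto Φ⁻¹((rank − ½)/m) — a rank-based inverse-normal
transform, chosen because every downstream model assumes Gaussian
phenotypes. An alternative mode mapping all features onto a common empirical
distribution exists behind a flag. Finally each sample column is z-scored
over its non-missing entries (sample SD, ddof = 1). Expression phenotypes
take log2((count + 0.5)·10⁶/(library + 1)) through the same chain; no
mean–variance precision weights are computed — all observations are weighted
equally, which the recovery experiments here do not require and which keeps
the chain's invariances exact.

Two consequences worth knowing: the log2 step is monotone, so after the
rank transform it only determines which entries are missing; and per-group
quantile normalization equalizes group distributions — for cross-tissue
differential splicing the chain must therefore run on the **combined**
multi-tissue matrix (as `analysis/03` does), never per tissue.

## Differential splicing

Per feature, tissue effects are tested in y = animal(random) +
experiment(fixed) + tissue(fixed) + e. The single variance ratio
λ = σ²ₐ/σ²ₑ is profiled on the eigenbasis of ZZ′ (Z the animal incidence),
REML-optimized in log λ on [−14, 14] with an explicit λ = 0 boundary check.
The tissue term gets a Wald F with Satterthwaite denominator df: each
eigen-contrast of L·Cov(β̂)·L′ receives ν = 2f²/Var(f), with Var(f) by the
delta method from the numerical Hessian of the restricted likelihood in
(σ²ₐ, σ²ₑ); the per-contrast ν are pooled through E = Σν/(ν−2),
ddf = 2E/(E−q). Marginal (type-III-style) tests are used. The fit matches
`lmerTest` to three figures on shared fixtures and collapses exactly to the
OLS two-way ANOVA when each animal is observed once. Breed effects are plain
OLS on a two-level indicator, identical to the equal-variance two-sample t.

A gene is called differentially spliced when ≥1 exon and ≥1 **adjacent**
intron both reach q < 0.1. Adjacency is undefined in the field's informal
usage; here an intron is adjacent when intron.start = exon.end + 1 or
intron.end = exon.start − 1, with a fallback to the nearest same-gene intron
within 10 kb (the rule used is recorded per call). The combined threshold is
reported as the product of the stage cutoffs (0.1 × 0.1 = 0.01). Gene
ranking for export uses the minimum exon-q × intron-q product.

## cis QTL scans

For each feature, SNPs with position in [start − 1 Mb, end + 1 Mb] on the
same chromosome are tested by OLS of the phenotype on alt-allele dosage,
after projecting out covariates (Frisch–Waugh residualization; breed is the
standard covariate in the mixed-breed milk cohort). The window anchors at
the feature *boundaries* — the permissive reading of "within ±1 Mb of the
feature" — so upstream and downstream SNPs at equal distance are treated
symmetrically. Pairs with fewer than (#covariates + 3) complete
observations, or with no residual dosage variance, are skipped; no
regularization is applied. FDR (Storey q-values; BH behind a flag) is
computed within each (tissue × phenotype kind) scan, never pooled. The
Storey π₀ uses a cubic fit over the λ grid 0.05–0.95 evaluated at 0.95,
clamped to (0, 1], with π₀ = 1 below 100 p-values.

sQTL calls join the exon-inclusion and intron-excision scans: one call per
(SNP, exon) with exon q < 0.1 and q < 0.1 for the same SNP against an
adjacent intron. eeQTLs and geQTLs use q < 0.01 on the expression scans.
These stringencies are deliberately as printed in the field's convention and
are not directly comparable between sQTLs (conjunction of two 0.1 cutoffs)
and the expression QTLs (single 0.01 cutoff).

## Local genomic relationship matrices and bivariate REML

The local GRM uses SNPs in the feature's ±1 Mb window, centered dosages, and
the scaling G = WW′/Σ2p(1−p) (VanRaden's first method; a per-SNP
standardized ZZ′/m mode is available behind a flag). Monomorphic SNPs are
excluded, <10 SNPs is an error, and a ridge of 10⁻⁶ on the diagonal keeps
small local windows invertible.

The two-trait model places cov(g) = K ⊗ G with K the 2×2 genetic
(co)variance matrix and a residual covariance estimated **only when the
sample sets overlap** (it is structurally absent for disjoint cohorts such
as liver vs muscle). The covariance model is linear in
(vg₁, cov_g, vg₂, ve₁, ve₂, cov_e), so the unconstrained and r = 0 fits use
AI-REML: Newton steps on the average-information matrix, taken in
transformed coordinates (log variances, atanh correlations) so every iterate
stays interior; steps are halved until the restricted likelihood does not
decrease, with a scaled-gradient fallback — accepted iterations are monotone
by construction. Convergence is |Δℓ| < 10⁻⁸·(1 + |ℓ|) or 200 iterations.
The atanh coordinates saturate at |z| = 12 (|r| within ~10⁻¹⁰ of 1), which
bounds the likelihood in degenerate cases (e.g. duplicated phenotypes) where
it would otherwise diverge on the singular-correlation boundary.

When both traits share the same individuals, eigendecomposing G reduces the
model to n independent 2×2 blocks and every REML quantity is O(n) per
iteration; overlapping/disjoint designs use dense matrices (O(n³), fine at
cohort sizes here). The r = 1 constraint is nonlinear in the parameters and
is fit by Nelder–Mead on log-variance coordinates with cov_g tied to
√(vg₁vg₂) and the same correlation saturation.

r_lg = cov_g/√(vg₁vg₂) is reported with a delta-method SE from the inverse
AI matrix. LRTs: against 0, 2Δℓ ~ χ²₁; against 1 the null sits on the
boundary and the ½χ²₀ + ½χ²₁ mixture applies; a statistic of zero reports
p = 1. A genetic variance estimated at its floor leaves r_lg undefined
(reported missing), and a non-converging constrained fit reports its p as
missing rather than guessing.

## Meta-analysis and overlap

The multi-tissue statistic (Σtₙ/√N)² ~ χ²₁ assumes cross-tissue independence
of t under the null; shared-animal designs (blood/milk) violate this, and an
optional effective-N correction (divide by 1′R1/N with R the estimated
cross-tissue t correlation) is provided behind a flag, default off to match
standard usage. The validation design filters candidate pairs to p < 0.05 in
each combined tissue, flags meta p < 10⁻⁵, and cross-tabulates against a
held-out tissue at p < 0.05 with a Fisher overlap test. Two-cohort GWAS
effects combine by inverse-variance weighting; the multi-trait t′V⁻¹t
estimates V from SNPs with all |t| < 2 to avoid signal contamination.
Overlap enrichment is one-sided (greater), with the union of analyzed SNPs
as the default background. A greedy ±1 Mb lead-SNP clumping utility is
included but not validated against any external locus catalogue.

## The synthetic cohort

The generator emulates the study design rather than its raw reads: a dairy
cohort (default 131 individuals, 80% breed A) measured in blood and milk,
plus disjoint liver (35) and muscle (41) cohorts; 20 genes of five 200-bp
exons; 60 SNPs per ±1 Mb window with AR(1) linkage disequilibrium (haplotype
copying probability = target adjacent-SNP correlation, default 0.5), allele
frequencies uniform on [0.05, 0.5], Hardy–Weinberg within breed, optional
Balding–Nichols breed differentiation (Fst, default off).

Gene-level log2 expression is baseline (log2 of depth 500) + dosage effect +
a SNP-mediated local polygenic term + N(0, 0.4) noise; the polygenic term's
per-SNP effects are bivariate normal across tissues with correlation
`cross_tissue_rg` (default 0.8), so the LGRM-REML estimand equals the
configured value exactly. Counts are negative binomial with dispersion 0.1 —
the standard bulk RNA-seq assumption; no count distribution is implied by
the phenotype chain itself. geQTL effects (default 1 residual-SD per alt
allele on the log2 scale) act on one causal SNP per gene at MAF ≥ 0.1 near
the gene; sQTLs shift the middle exon's usage through a logistic in dosage
calibrated so usage(dose 2) − usage(dose 0) equals `usage_shift` (default
0.3), with adjacent intron weights moving oppositely. Per-(gene, tissue)
usage offsets (SD 0.08) create genuine tissue-differential splicing;
optional breed shifts on designated genes create breed-differential
splicing and, combined with Fst, breed confounding. Multi-causal
architectures are out of scope — one causal SNP per gene.

What passing tests therefore show: the estimators are calibrated and
recover effects under NB noise, LD, breed structure, and the configured
sharing. What they do not show: robustness to alignment artifacts, coverage
bias, RNA degradation, imputation error, or multi-causal and haplotype
effects — none of which the generator emulates.

## Problem sizes and runtimes

The test suite and the acceptance script run at desk scale by design: 50
simulation replicates for the sQTL recovery and null-FDP experiments
(n = 200, 2 genes, 40 SNPs each), 50 replicates per true value for the
genetic-correlation recovery (n = 300 shared samples, 100-SNP window,
h² = 0.5), 1000 null features for the mixed-model type-I error, and
10,000–30,000 draws for the meta-statistic calibrations. At these sizes the
full suite takes well under a minute of compute beyond the REML experiments.
Monte-Carlo tolerances in the tests match those sizes.

## Known limitations

- Storey's π₀ uses a cubic-polynomial smoother, not the original smoothing
  spline; at the grid size used the difference is negligible and the BH
  fallback is exact.
- Satterthwaite df relies on a numerical Hessian; with variance ratios at
  the boundary it degrades gracefully to the OLS residual df.
- The r = 1 constrained fit is derivative-free and can report a conservative
  (smaller) likelihood on hard instances, making p_vs_1 conservative.
- The validation demo in `analysis/06` has few candidate pairs because the
  weak-tissue filter (muscle, n = 41) is deliberately part of the design;
  its cross-tabulation is illustrative, while the meta-power property is
  established by the test suite at controlled sizes.
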