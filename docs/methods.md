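# Methods

`lipidgwas` implements the post-genotyping analysis chain for a
genome-wide association study of a high-dimensional, correlated lipidome,
together with a synthetic-cohort generator that makes every stage testable
at desk scale. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic data do and do not show.

## Phenotype preparation

Raw lipid-species levels are regressed on covariates (age, sex, site, and
whatever else the caller supplies, e.g. genetic PCs from the GRM module) by
per-species least squares over that species' complete cases, and the
residuals are inverse-normal transformed with the Blom offset,
`Phi^{-1}((r - 3/8)/(n + 1/4))` with average ranks for ties. Blom is the
common GWAS convention; the offset only shifts scores by O(1/n) relative to
other choices. Missing values are preserved through both steps; association
testing always uses per-species complete cases.

The multiple-testing budget comes from PCA of the *mean-imputed* phenotype
matrix: the effective trait count `k` is the smallest number of principal
components whose cumulative explained variance strictly exceeds 90%. Mean
imputation is used for this step only. The strict exceedance rule carries a
1e-10 guard so that exactly-tied eigenvalue spectra (cumulative share
exactly 0.9) do not flip on float rounding. Derived thresholds are plain
Bonferroni quotients: genome-wide 5e-8 / k, nominal 0.05 / k, and
locus-count-corrected variants thereof.

## Trait clustering

Multivariate testing needs trait sets whose correlation matrix is well
conditioned. The pipeline (i) computes pairwise-complete absolute Pearson
correlations of the transformed phenotypes; (ii) iteratively removes one
member of each pair with |r| > 0.8 — the member with the larger mean |r|
against the remaining traits, ties broken toward the lexicographically
later id, so the more redundant trait goes; (iii) runs average-linkage
agglomerative clustering where each trait's feature vector is its row of
the |r| matrix and dissimilarity is the Euclidean distance between rows,
cut at an explicit cluster count (a parameter standing in for visual
dendrogram inspection), optionally within partition groups (e.g.
glycerolipids clustered separately from the rest); and (iv) within each
cluster iteratively removes the member with the largest variance inflation
factor, `VIF_j = 1/(1 - R^2_j)` from regressing member j on the others,
until max VIF < 5. A perfectly collinear member has infinite VIF and is
removed first; this is a normal path, not an error. After (ii) and (iv)
the within-cluster correlation matrix is invertible.

## Univariate association

The default per-variant test is OLS of the prepared phenotype on dosage
(intercept included) with a two-sided Wald p from the normal approximation
— appropriate for unrelated samples at thousands of observations. A
one-component linear mixed model is provided for structured cohorts: the
genetic variance share is estimated once on the null model by profiling the
likelihood in the GRM eigenbasis, then each variant is tested by GLS in
that basis. With an identity GRM the two agree to numerical precision.
Variant filters keep MAF >= 0.002 and INFO >= 0.8, boundaries inclusive.
The genomic inflation factor is the median observed 1-df chi-square over
the theoretical median (~0.4549).

## Multivariate association by canonical correlation

Per-trait summary statistics are standardized to the genotype-phenotype
correlation scale,

    b_j = beta_j / (sqrt(N_j) * se_j),

and the trait-trait correlation `S_YY` is estimated either as the Pearson
correlation of the standardized-effect columns across the (null-dominated)
genome or directly from phenotypes, then shrunk toward the identity with
the smallest coefficient making the minimum eigenvalue >= 1e-3. The
single-SNP canonical correlation is `r^2 = b' S_YY^{-1} b`, tested with
Bartlett's chi-square

    chi2 = -(N - 1 - (1 + q + 1)/2) * ln(1 - r^2),  df = q,

with N the mean per-trait sample size at the variant and q the cluster
size. Bartlett's factor is the standard CCA asymptotic with one genotype
variable; for small r it reduces to N r^2, and for q = 1 it matches the
univariate z^2 to within 0.5% at r ~ 0.05. The optimal combination weights
`a ~ S_YY^{-1} b` are scaled to `a' S_YY a = 1` with the sign fixed so
`a'b >= 0`; summing traits with these weights and re-standardizing yields
the linear combination phenotype (LCP) whose univariate chi-square
approximates the multivariate statistic at the lead variant, enabling
region-wise fine-mapping of multivariate signals with the univariate
machinery.

**Rare-variant permutation control.** For variants with MAF < 0.05 that are
genome-wide significant in the multivariate but in no univariate analysis,
a genomic-control factor is estimated by permuting the genotype vector
(phenotypes fixed, so the trait correlation is preserved), recomputing the
exact per-trait standardized effects and the chi-square for each
permutation, and taking the median permuted chi-square over the theoretical
median at df = q; the observed chi-square is divided by lambda before the
p-value. The default here is 10,000 permutations. A measurement worth
recording: with the exact OLS recomputation this package uses, the
rare-variant statistic is already essentially calibrated — lambda at
MAF 0.005, q = 10, n = 2000 measures 1.000-1.005 across genotype draws at
100,000 permutations — so the correction is nearly neutral. Analysis
stacks that approximate the per-variant test (mixed-model score tests,
external CCA software) can show real inflation here, which is exactly what
this machinery corrects; with the built-in test it is a safety net, not an
active correction.

**Driver traits.** A multivariate association is decomposed by a
decremental search: repeatedly drop the trait whose exclusion leaves the
smallest multivariate p (the least-contributing member), recording
`BIC(S) = -chi2(S) + |S| ln N` at each subset; the minimum-BIC subset on
the path is the optimal set and its members the driver traits (flagged
"metaphat-like" in output). With correlated cluster members a null trait
can legitimately enter the optimal set: conditioning on a trait correlated
with the causal one lowers residual variance and raises the chi-square by
more than the BIC penalty. This is expected behavior of BIC-guided subset
selection on correlated traits, not a defect; with independent members the
causal trait is isolated.

## Fine-mapping

Causal configurations of up to `K_max` variants (default 3) are enumerated
exhaustively. For configuration C the z-scores restricted to C are
multivariate normal: `N(0, R_C + N sigma^2 R_C R_C)` under C and
`N(0, R_C)` under the null, with R the signed in-sample dosage correlation
and sigma = 0.05 the prior SD of a standardized causal effect. The prior is
independent inclusion at pi = 1/m truncated at K_max; both are
configurable and logged. Posteriors are normalized over all enumerated
configurations; PIP(v) sums the posterior over configurations containing
v, and the MAP causal count k* maximizes the per-size posterior mass.
Enumeration is exact at desk scale (regions are size-capped per K), which
is the point: it replaces stochastic search with something a brute-force
oracle can check to 1e-10.

Per-signal 95% credible sets use a swap construction on the MAP
configuration: fix the other k* - 1 variants, let one slot range over all
candidates, renormalize those configuration posteriors, and take the
smallest descending-PIP prefix reaching 0.95. For k* = 1 this reduces to
renormalized single-variant posteriors. A set is informative when the
minimum pairwise r^2 among members is >= 0.1; the representative is the
top-PIP member unless a functional variant (severity-ordered consequence
list from transcript ablation down to splice-region) in the set has
r^2 > 0.95 with it, in which case the functional variant with the largest
r^2 substitutes. Regions overlapping the MHC (chr6:25-34 Mb) skip
fine-mapping and fall back to the GWAS lead variant. A non-PSD LD matrix
is ridge-repaired (1e-6 diagonal) and flagged.

## Locus definition

Per trait, lead variants are taken iteratively by ascending p; each opens a
±1.5 Mb region, overlapping regions merge (lowest-p lead wins, others
become secondary), and a merged region wider than 6 Mb has its per-lead
half-windows multiplied by 0.9 repeatedly until it fits or the pieces
separate. The stopping rule — no genome-wide-significant variant outside
any region — is checked against the final shrunk regions, so shrinking can
expose further leads; this preserves the invariant that every significant
variant lies inside some region. Fine-mapping representatives are merged
into signals (connected components at r^2 >= 0.1 on the same chromosome),
signal spans are the unions of their contributing regions, and overlapping
spans form non-overlapping physical loci. A locus is novel when every lead
has r^2 < 0.1 with all known variants present in-sample and no absent
known variant lies within ±1.5 Mb (the proximity fallback replacing
external LD-proxy lookups — the one deliberate deviation from reference-
panel proxying, logged per call). Naming: gene of a missense
representative if any, else the gene overlapping the lowest-p lead, else
the nearest gene by edge distance (ties toward the upstream gene).

## Endpoint integration

Binary endpoints with at least 50 cases are tested per variant by logistic
regression (dosage + covariates, Wald two-sided p), with an L2-penalized
fallback flagged on separation; tiers are nominal and genome-wide levels
divided by the endpoint count. The effective sample size
`N_eff = N theta (1 - theta)` (theta the case proportion) is handed to
endpoint fine-mapping on logistic z-scores through the same enumeration
engine, keeping both sides of the colocalization coherent. Colocalization
between informative credible sets is
`CLPP = sum_s PIP_T(s) PIP_D(s)` over shared variants, called at
CLPP > 0.01. External risk-variant lookups resolve absent variants to the
best in-sample proxy with r^2 > 0.8 within 500 kb, align effects to the
risk allele, and report three significance tiers.

## Synthetic cohort

The generator emulates a biobank lipidome cohort at the statistical level.
Genotypes: a Gaussian copula per LD block — each haplotype thresholds a
latent AR(1) process (default rho 0.6, block size 20) at the
allele-frequency quantile, two haplotypes sum to a genotype — over a
three-class MAF spectrum (60% common 0.05-0.5, 25% low-frequency
0.01-0.05, 15% rare 0.002-0.01; floor 0.002). Imputation quality is
emulated by blending toward the expected dosage, `(1-e) g + 2 e maf` with
e ~ U(0, 0.1), and INFO recorded as dosage variance over `2p(1-p)`, giving
the MAF/INFO filters real work. Lipidome: species get a lipid-class factor
(default loading 0.6, so within-class r ~ 0.36), fixed covariate effects
(standardized slopes: age 0.10, sex 0.20, site 0.05), planted genetic
effects (standardized slopes; sign-canceling multi-trait configurations
must satisfy |sum beta| < max |beta|; rare-large effects must sit on
MAF < 0.05 variants), a polygenic background filling the gap between the
planted variance and the per-species heritability target, and independent
noise making total variance 1. Default heritability targets span 0.12-0.35
by lipid class, sphingolipid-like classes highest, matching the 0-0.45
range reported for plasma lipid species. Missingness is MCAR (default
2%). Endpoints follow a logistic liability model — case probability
`expit(alpha + sum gamma_k dosage_k)` with the intercept solved for the
target prevalence — so planted per-dosage log-odds ratios are exact;
endpoints with an expected case count below 50 are flagged excluded. Every
planted parameter lands in a ledger that round-trips through TSV.

What the generator does *not* emulate: genotyping and imputation error
structure beyond the INFO blend, population stratification and relatedness
(samples are exchangeable; the mixed model is exercised against constructed
GRMs instead), non-Gaussian lipid distributions beyond what INT absorbs,
batch effects, and real LD beyond blockwise AR(1). Passing tests therefore
establish the correctness and calibration of the statistical machinery
under its stated assumptions, not robustness to those real-data
complications.

## Numerical choices and degenerate inputs

- Zero-variance dosages yield p = 1 with the SE flagged degenerate rather
  than an error; monomorphic variants are dropped from the GRM with a
  warning; constant phenotypes and all-missing species are errors.
- `S_YY` shrinkage uses the smallest alpha with min eigenvalue >= 1e-3;
  the amount is logged on the result object.
- Haseman-Elston regresses pairwise phenotype products on GRM entries; its
  SE is a delete-one-sample jackknife (closed form from per-sample partial
  sums), because pairs sharing a sample make the naive regression SE
  anti-conservative by ~1.5x at n = 4000. The "reml" estimator is
  single-component profile ML on the GRM eigenbasis (nonzero spectrum from
  the SVD of the standardized dosage matrix, null space handled
  analytically), SE from the expected information. Estimates are clamped to
  [0, 1] with the raw value kept and the clamp flagged.
- Ties: pair pruning and VIF pruning break toward the lexicographically
  later id; LD pruning drops the lower-MAF variant, then the later
  position; lead-variant ties break by position then id.
- Permutation inflation estimation is bit-reproducible given a seed and
  batched so memory stays flat.

## Problem sizes

The verification suite and the reproduction script run, by design, at desk
scale: 1e4 null variants at n = 5000, q = 5 for calibration; 1e4
permutations (of the production default 1e5-scale procedure) for the
rare-variant factor at MAF 0.005, q = 10, n = 2000; 50 replicates for the
sign-canceling power comparison; 200 single-causal regions for PIP
calibration; 20 cohorts at n = 4000 with 800 GRM variants for
heritability recovery. These sizes give Monte-Carlo error comfortably
inside the asserted bands while keeping a full run under a minute.

## Known limitations

- Exhaustive enumeration caps region sizes (default 2000 variants for
  K <= 2, 200 for K = 3); production-scale regions require raising the
  budget or lowering K_max.
- The LCP is built from the lead variant's weights; weights at other
  variants in the region differ, so LCP-GWAS is a region-specific
  approximation (as intended).
- The proximity fallback for absent known variants is cruder than
  reference-panel LD proxying and can over-call non-novelty near known
  loci.
- Logistic endpoint fine-mapping treats z-scores with N_eff as if linear;
  this is the standard case-control approximation and degrades for very
  unbalanced endpoints.
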