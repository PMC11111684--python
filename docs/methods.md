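# Methods

`retrowas` implements a retrotranscriptome-wide association study (rTWAS):
a TWAS whose feature panel contains locus-resolved human endogenous
retroviruses (HERVs) alongside canonical genes.  Because the real cohorts
such a study needs (post-mortem brain expression with matched genotypes,
and large psychiatric GWAS) are access-restricted, the package ships a
first-class synthetic-data module that generates every input with known
ground truth, and the statistical machinery is validated against that
truth plus independent oracles.  This note records the models, the
defaults and why, and what the synthetic validation does and does not
establish.

## Synthetic cohort model

**Genotypes.**  Haplotypes are drawn from a latent AR(1) Gaussian per LD
block and thresholded at the per-SNP minor-allele frequency; two
independent haplotypes sum to a diploid dosage in {0,1,2}.  Thresholding
attenuates correlation, so the latent autocorrelation is calibrated per
adjacent pair — the bivariate-normal orthant probability is evaluated via
Owen's T and inverted by bisection — such that the realised *genotype*
correlation matches the requested `rho`.  Two binary markers with margins
p1 != p2 have phi correlation capped at sqrt(p1 q2 / (q1 p2)); within a
block the MAF therefore drifts slowly (an AR(1) on the MAF-generating
latent whose coefficient approaches 1 as `rho` does), mirroring the fact
that SNP pairs in strong LD have near-identical allele frequencies.
Blocks are mutually independent; in the bundled study each block sits on
its own chromosome (20 blocks x 100 SNPs, `rho` = 0.6, MAF in
[0.05, 0.5]).

**Expression.**  Each feature's latent (unit-variance) log-expression is
`sqrt(h2) g + sqrt(1-h2) e`, where `g` is the standardized genetic value
of 1–3 causal cis variants and `e` optionally contains a shared planted
module factor and covariate effects.  Counts are Poisson with rate
`exp(mu_class + latent)`: integer, overdispersed, and class-specific —
the HERV mean natural-log expression (2.5) sits well below the gene mean
(5.0), reproducing the observation that HERV loci are expressed at much
lower levels than neighbouring genes.  The default cis-h2 is 0.2 with
60% of features cis-regulated at all; the one trait-mediated HERV gets
h2 = 0.4.  These are stand-ins chosen to be realistic for brain eQTL
panels, not estimates of any particular locus.

**GWAS summary statistics.**  Per LD block,
`z = sqrt(N) R b + eps`, `eps ~ MVN(0, R)`, where the joint per-SNP
effect `b` sums `alpha_f * b_eqtl,f` over mediating features (all on
standardized scales) and `R` is the empirical block LD.  This is exactly
the model the association stage assumes, so the pipeline's null
calibration is a meaningful check of the statistic, not of the generator.
Defaults: GWAS N = 100,000, mediation effect alpha = 0.1 for the planted
HERV — a well-powered GWAS of a moderately mediated trait.

**Fragments.**  Fragment sources follow Categorical(pi); a fragment from
a homology group is, with probability 0.8, reported against every group
member.  Candidate scores are Gaussian: `match_score` 200 for the true
source, 200 − 80 for homologous copies (about ten divergent sites in a
local alignment), both with sd 40.  With Gaussian noise sd sigma and mean
gap Delta, the true source posterior is proportional to
`exp(s * Delta / sigma^2)` — a softmax with scale sigma^2/Delta = 20 — so
the EM engine's default likelihood is exactly calibrated for these
fragments and its estimate of pi is consistent.  Deterministic scores
(no noise) would make the softmax misspecified and leave an O(0.01)
asymptotic bias.

**Seeds.**  Every generator takes an explicit seed; a master seed fans
out to stages by fixed offsets.  Identical seeds reproduce every output
byte-identically.

## EM quantification

The reassignment model treats each fragment as drawn from one of K
features (plus a reserved no-feature slot for off-target material, with
pseudo-score = the fragment's minimum candidate score − 2 scales) with
mixture weights pi.  E-step: posterior over the fragment's candidates
proportional to `pi_j exp(s_ij / scale)`.  M-step (MAP under a symmetric
Dirichlet with strength alpha = 1e-3): `pi_j = (sum_i p_ij + alpha) /
(N + K alpha)`.  Convergence when the log-posterior moves < 1e-6
(max 200 iterations); the log-posterior is asserted non-decreasing in
every test run.  Count materialisation offers `best` (argmax posterior,
ties to the lowest feature index and logged), `fractional`, and `unique`;
`best` is the default.

## Expression preparation

The expression filter keeps features with count >= 6 **and** TPM >= 0.1
jointly in the same sample, in at least 20% of samples — the stricter,
GTEx-style reading of the joint threshold.  TMM normalisation follows the
doubly-trimmed (30% of M, 5% of A, from each tail), precision-weighted
mean of M-values against the sample whose upper quartile is closest to
the mean upper quartile, with factors rescaled to geometric mean 1.
logCPM uses `log2((count + 0.5) / (TMM-effective library + 1) * 1e6)`.
Genotype PCs come from greedily LD-pruned (r^2 < 0.2), sqrt(2p(1-p))-
standardized dosages.

Covariate adjustment regresses each feature on institution, diagnosis,
RIN, sex, PMI, ordinal age bins (17–29, 30–49, 50–69, 70–89, 90+), ten
genotype PCs and surrogate variables, dropping collinear design columns
by QR with a warning.  Surrogate variables are the top principal
components of the known-covariate residual matrix — a deterministic
proxy for iterative surrogate-variable estimation.  Their number follows
the sample-size rule (30 for N in [150, 250], 60 above 350, linear in
between, 15 below 150).  That rule presumes transcriptome-scale feature
panels; on a small panel rule-many residual PCs are noise-driven and
absorb per-feature (including cis-genetic) variance.  The pipeline
therefore caps the rule with a parallel-analysis estimate: singular
values of the residual matrix are compared with the 95th percentile of
column-permutation nulls and only the leading run of exceedances counts
as genuine latent factors.  On the bundled cohort this recovers exactly
the planted module factors.

## Genotype QC

Hardy–Weinberg is a 1-df chi-square against expected counts from the
sample allele frequency (the exact enumeration test is kept as a test
oracle only).  Variant filters: MAF > 0.05, HWE p >= 5e-6, missingness
< 0.05, strand-ambiguous (A/T, C/G) pairs removed.  Relatedness uses the
method-of-moments IBD estimator (pihat = P(IBD=1)/2 + P(IBD=2)) from
IBS counts and panel allele frequencies, computed on LD-pruned markers.
Because a desk-scale panel (~10^3 markers) gives the estimator a sampling
sd of 0.05–0.1 for unrelated pairs, removal requires pihat to exceed
both the nominal 0.2 and a data-driven noise floor (median + 5 MAD of
all pairwise estimates); duplicates and first-degree relatives
(pihat 0.5–1) are far above both.  Of a related pair, the member with
higher missingness is dropped (ties: the later sample id).  Sumstat
harmonisation keeps exact allele matches, sign-flips swapped alleles,
and drops strand-ambiguous or irreconcilable records, with MAF > 0.05
and INFO > 0.80 filters when those columns exist; every action is
counted in a report.

## Cis-heritability and weights

The cis window is the feature span +/- 500 kb (a ~1 Mb window in total;
configurable).  Heritability comes from the single-component mixed model
`y ~ N(0, s2_g XX'/m + s2_e I)` profiled over the total variance and
optimised in one dimension over h2 via the eigendecomposition of the
local relatedness matrix.  The LRT against s2_g = 0 uses the boundary
mixture `0.5 chi2_0 + 0.5 chi2_1` (the component sits on the boundary of
its parameter space); the gate is nominal p < 0.01.  Under the null this
calibrates to about a 1% rejection rate in the acceptance suite.

Weights for gated features: top eQTL (single marginal-OLS coefficient at
the max-|z| SNP), lasso and elastic net (mixing 0.5) along a data-driven
penalty path with the penalty chosen by inner 5-fold CV subject to
in-sample R^2 <= h2 (an over-fitting guard; the strongest penalty is used
if none is feasible), and BLUP (`w = (X'X + m(1-h2)/h2 I)^{-1} X'y`).
Lasso/enet are fit on unit-variance y and rescaled, which makes every
method exactly equivariant to rescaling of the phenotype.  Methods are
compared by 5-fold cross-validated squared correlation with
standardization refit inside training folds; ties break toward fewer
nonzero weights, then a fixed method order.  The winner is refit on the
full data; features whose best CV R^2 is not positive are excluded with
a log entry.  A Bayesian sparse regression variant is deliberately not
offered; the four methods above reproduce the selection logic without
its convergence fragility.

## Association, conditional analysis, fine-mapping

The TWAS statistic is `Z = w'z / sqrt(w'Rw)` with R the panel LD
correlation shrunk as `(R + 0.1 I)/1.1` (unit diagonal preserved;
stabilises the quadratic form on small panels; logged in results).
Bonferroni correction uses the number of features actually tested per
trait, and the per-trait threshold 0.05/m is reported.  Features with
under half their weight SNPs present in the summary statistics are
flagged `low_coverage` but retained.

Significant features whose padded cis windows (+/-100 kb) overlap merge
transitively into loci.  Within a locus, greedy forward selection adds
the feature with the smallest conditional p given the current set while
below the per-trait threshold; conditional statistics use the predicted-
expression correlation `Omega_ij = w_i'Rw_j / sqrt(w_i'Rw_i w_j'Rw_j)`,
with candidates of conditional variance < 1e-4 flagged collinear and
singular `Omega_SS` ridged at 1e-6.  Joint statistics for the selected
set are the GLS effects `Omega_SS^{-1} Z_S` standardized by the diagonal
of `Omega_SS^{-1}`.  SNP-level conditioning subtracts
`rho_kS Omega_SS^{-1} Z_S` with `rho_kj = (Rw_j)_k / sqrt(w_j'Rw_j)`.

Fine-mapping enumerates all causal configurations of size <= 3 (hard cap
25 features per block; larger blocks must be split) plus the null; a
configuration c has likelihood `N(Z; 0, Omega + v Omega[:,c] Omega[c,:])`
with prior `p^|c| (1-p)^{K-|c|}`, defaults prior p = 1e-3 and effect
variance v = 40 (both config keys, both logged).  PIPs sum the normalised
posterior over configurations containing the feature; the 90% credible
set greedily adds features by PIP until the mass of configurations fully
inside the set reaches 0.9.  A feature is **high confidence** iff it is
in the jointly selected set and has PIP > 0.5; the intermediate tiers
(Bonferroni-only, joint-only, PIP-only) are also emitted.

## Co-expression network

Signed adjacency `a_ij = ((1 + cor_ij)/2)^beta` on Pearson correlations
of TMM logCPM, with beta = 12 by default (the smallest power whose
approximate scale-free fit R^2 reaches 0.8 is available via `pick_beta`).
Topological overlap `TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`
filters spurious edges.  Modules: average-linkage clustering of 1 − TOM,
a static cut at height 0.99, clusters under 30 features to grey, then
iterative merging of modules whose eigengenes (first PC of standardized
module expression, oriented positive on the module mean, unit norm)
correlate above 0.75.  A static cut plus eigengene merging stands in for
dynamic tree cutting; the cut height is a config key and the planted-
module fixtures are recovered exactly (ARI = 1).  Colours are assigned
by descending size from the conventional palette (largest = turquoise,
unassigned = grey).  GO enrichment is hypergeometric (upper tail) over
the canonical-gene universe only — HERVs are excluded, since module
function is read off the genes — with Bonferroni correction across all
module x term tests and `enrichment_ratio = observed/expected`.

## Problem sizes and what the validation shows

The bundled study runs 200 samples x 2,000 SNPs x 120 features (40
HERVs, one mediated); the statistical suites use n = 400, m = 100 with
100 replicates for REML calibration, 1,000 feature-runs for TWAS null
calibration, 50 loci for fine-mapping power, and 20,000 fragments for EM
recovery — sizes chosen so the full suite runs on a laptop in minutes
while keeping Monte-Carlo error well inside the asserted tolerances.

Passing these suites shows the machinery is correct and calibrated under
the generative model it assumes: LD from block-AR(1) haplotypes,
expression mediation that is linear and cis-only, softmax-consistent
alignment scores, and GWAS noise matched to the panel LD.  Real data
violate all of these in places (long-range LD and structure, trans
effects, context-dependent mediation, alignment artefacts, case-control
sampling), so the tests certify the implementation, not the biology.

## Known limitations

- The no-feature slot models off-target fragments with a single
  pseudo-score rather than a genome-wide background model.
- Surrogate variables are residual PCs, not the iteratively reweighted
  estimator; on transcriptome-scale panels the two differ.
- The IBD noise floor means true relatives with pihat just above 0.2
  could survive QC on very small marker panels.
- Fine-mapping enumerates configurations; blocks above 25 features are
  refused rather than approximated.
- Family-level HERV aggregate quantification, trans-eQTL weights,
  sex-stratified weights and genotype imputation are out of scope.
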