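# Methods

This note documents the statistical models, the synthetic data the
package generates, the numerical choices, and the limits of what the
tests demonstrate.

## Synthetic cohorts

The generator (`pgnet.synthetic`) is first-class, tested code; it
defines the study conditions under which every estimator is
validated.

**Genotypes.** Variants are partitioned into contiguous LD blocks.
Each haplotype is a latent AR(1) Gaussian (adjacent-variant
correlation `rho`, default 0.7) thresholded at Φ⁻¹(MAF); two
independent haplotypes sum to a dosage in {0, 1, 2}.  This yields
Hardy-Weinberg genotypes with tunable within-block r² and independent
blocks, without a haplotype panel.  The expected dosage correlation
of adjacent variants is the thresholded-bivariate-normal indicator
correlation; the test suite checks the empirical correlation against
that quantity computed by numeric integration.  Allele frequencies
and allele labels are a fixed reference panel shared by all cohorts
of the same shape, so multi-cohort meta-analysis sees consistent
alleles; genotype draws still vary with the cohort seed.  Defaults:
2,000 samples, 240 variants in 12 blocks, MAF ∈ [0.05, 0.5].

**Disease trait.** Liability = √h² · (standardized causal score) +
fixed covariate loadings (0.10 on standardized age and sex) +
√(1−h²) · N(0,1); a sample is a case iff liability exceeds the
(1 − prevalence) quantile of the total liability SD.  Defaults: 8
causal variants, h² = 0.3 on the liability scale, prevalence 0.10.
The implied marginal per-allele log-odds has no closed form; the test
suite computes it as the population minimizer of the expected
logistic likelihood given the exact genotype-conditional case
probabilities and verifies 95% CI coverage of the association module.

**Proteins.** Each measured protein is coded by one gene; abundance =
Σ cis effects (variants inside the gene interval) + Σ trans effects
(elsewhere) + 0.20·age_std + 0.30·sex + 0.05·age_std·sex + N(0,
noise²).  Effect sizes are drawn N(0, sd²) with sd 0.4 (cis) and 0.15
(trans) — cis effects dominate, as in plasma pQTL atlases.  When a
gene contains a disease-causal variant, the cis effect is placed on
it, creating the genetically mediated proteins the causal-inference
phase is meant to find.  The measured panel covers the planted-module
genes first, emulating a targeted assay enriched for disease biology.

**PPI.** Preferential attachment from a two-node connected seed; each
new node attaches `min(m, existing)` degree-proportional edges
(m = 2), giving exactly 2(n−2)+1 edges and a scale-free degree tail.
A connected planted module is grown by uniform neighbor expansion;
disease-causal variants are drawn preferentially (fraction 0.6) from
the planted genes' windows, so gene scores light the module up.

**Seed discipline.** One global seed fans out to per-component child
seeds through fixed `SeedSequence` spawn keys (`component_rng`), so a
stage's inputs can be regenerated without re-running the others.
Every generator is a pure function of (spec, seed).

**What the generator does not emulate** — and therefore what passing
tests do not show about real data: recombination-map LD (AR(1) blocks
have no long-range structure), population stratification beyond PC
covariates, relatedness, imputation uncertainty (INFO is consumed,
never computed), assay batch effects, and X-chromosome dosage.

## Association and meta-analysis

Per-variant QC retains a variant iff MAF > 0.001, call rate > 0.95,
exact-test HWE p > 10⁻⁶, and (when INFO is supplied) INFO > 0.8 — all
strict inequalities.  The HWE test enumerates the conditional
distribution of heterozygote counts given allele counts.  Association
is plain covariate-adjusted logistic regression (sex, year of birth,
PCs); the two-step whole-genome-ridge machinery used at biobank scale
is unnecessary at synthetic scale.  Firth's Jeffreys-prior score
correction (tolerance 1e-8, max 100 iterations) is used on request or
as a fallback under separation; missing dosages are dropped listwise
(mean imputation by flag).  Meta-analysis combines two studies with
inverse-squared-SE weights after harmonizing alleles; strand-ambiguous
(A/T, C/G) variants are dropped when either study's EAF is within
0.08 of 0.5, else aligned by frequency.

The post-GWAS filter is read as *retain* MAF above the threshold; both
the 0.001 and 0.0001 thresholds are exposed in configuration.

## pQTL mapping

The scan projects the covariate design (intercept, centered age,
age², sex, age·sex, age²·sex, PCs) out of dosages and abundances once
(QR), then computes every (variant, protein) slope, SE (df = n − p −
1), and t-tail in closed form — algebraically identical to per-pair
OLS on the full design, which the tests assert against statsmodels.
p-values are stored as −log₁₀p (saturated at 5000 for exact fits) so
extreme associations survive double precision.  cis means same
chromosome and position within the gene interval ± 1 kb (inclusive,
1-based; the window is a knob since 1 kb is narrow by pQTL-atlas
conventions).

## Gene scores

T = Σⱼ χ²₁-quantile(pⱼ) with null Σλᵢχ²₁, λ from the eigenvalues of
the SNP correlation matrix (estimated from dosages, shrunk 1% toward
the identity).  The tail is computed exactly: rank-one and
equal-eigenvalue cases reduce to scaled chi-squares; otherwise Imhof
numerical inversion, switching to the Kuonen saddlepoint when the
quadrature cannot resolve p below ~10⁻⁸.  A Satterthwaite two-moment
approximation is retained for fast screening but is 2–3× conservative
in the far tail, which matters because tail gene p-values drive node
weights: z = Φ⁻¹(1−p), clamped to ±8.2 (≈ one-sided p = 10⁻¹⁶) to
keep module scores finite.

## Dense-module search

Zm = Σz/√k.  From each seed node, candidates within graph distance
d = 2 of the module are evaluated; admitting a distance-2 candidate
also admits the interior node of its (deterministic, sorted-BFS)
shortest path, counted in k, so modules stay connected.  The best
addition is accepted iff Zm_new > Zm_old·(1+r) with r = 0.1; ties
break lexicographically, so the search is fully deterministic.
`--strict-adjacent` restricts candidates to direct neighbors.

The multiplicative stopping rule sets an intrinsic module scale: for
flat weights Zm = z√k, and √((k+1)/k) < 1.1 once k ≥ 5, so
single-node growth stalls around k = 5–9 (interior-paired additions
stretch this to √((k+2)/k) < 1.1 at k ≥ 10).  The planted-module
recovery experiment is designed at that scale: a 100-node network
with an 8-node planted connected set whose genes carry z ∈ [2.5, 4]
over an N(0,1) background; the top-ranked module then recovers the
planted set at Jaccard ≥ 0.6 in well over 80% of seeded replicates.
On larger networks recovery degrades gracefully (path interiors and
background clusters dilute Jaccard) — a property of the greedy rule,
not of the implementation.

Normalization draws `b_norm` uniform random k-node subsets per module
size (they need not be connected) and standardizes Zm to Zn; top-1%
selection uses the ceiling of q·n with (Zn, Zm, seed) ordering.  The
permutation enrichment test draws same-size uniform node sets and
uses the +1 (add-one) empirical-p convention, so p ≥ 1/(B+1) always.

## Causal inference

Instruments are significant cis-pQTLs, greedily clumped by ascending
p at r² < 0.001 and harmonized to the outcome (palindromic variants
with EAF within 0.08 of 0.5 dropped).  Wald ratio SE uses the
first-order delta (SE_out/|β_exp|); IVW is the weighted
through-origin regression, identical to a fixed-effects meta-analysis
of per-SNP ratios with first-order weights; the weighted median
interpolates the ratio at cumulative weight 0.5 with weights
β_exp²/SE_out², SE by parametric bootstrap (n = 1000, seeded).  The
pleiotropy screen compares the observed leave-one-out weighted
residual sum of squares with parametric simulations under the
no-pleiotropy model (+1 p convention); it needs ≥ 4 instruments and
only the global test is provided — outlier removal is out of scope
since only the test outcome feeds the pipeline.

Colocalization: per-variant log-ABF = ½[ln(V/(V+W)) + z²W/(V+W)],
V = SE², with prior effect variance W = 0.15² for case-control
(log-odds) traits and 0.2² for quantitative traits — the conventional
defaults.  Hypothesis sums use log-sum-exp throughout; H3 is a
log-difference, exactly zero mass for single-variant regions.
Fine-mapping assumes one causal variant per region (500 kb windows
around index variants): PIP = normalized ABF, credible set = minimal
descending-PIP prefix reaching 0.95.  Multi-signal regions will
under-perform under this assumption; that is a stated limitation, not
a bug.  Both the 0.75 and 0.9 PP.H4 thresholds are exposed; 0.75 is
the default for "strong colocalization".

## Enrichment and triangulation

Over-representation is hypergeometric against the supplied panel
background (never the whole gene universe by default), BH-corrected
across tested sets; a set equal to the whole background gets p = 1 by
convention.  Triangulation's default rule is a ∧ (b ∨ c) — the
pQTL-associated set is mandatory, supported by either network branch;
a strict three-way intersection is available.  ANCOVA fits abundance ~
genotype + age + sex + age·sex (OLS, type-II F for the genotype
factor) with pairwise genotype contrasts as t-tests; levels with < 2
samples are dropped.  Loop mapping treats anchors as 0-based
half-open intervals, converts 1-based variant positions, normalizes
"chr" prefixes, and deduplicates links, so record order is
immaterial.

## Pipeline and reproducibility

Ten stages run in dependency order from one YAML config; each stage
writes TSVs plus a manifest entry (parameters, seed, SHA-256 hashes,
row counts), and completed stages are skipped unless forced.  All
randomized components take explicit seeds; two runs with the same
config are byte-identical.  Demo problem sizes (2,000 samples × 240
variants, 40 proteins, 300-node PPI; normalization 500 draws per
size, permutation B = 10,000) keep the full pipeline under ~5 seconds
while leaving every stage's statistics estimable; the calibration
experiments in the test suite use 100–500 replicates per property.

## Known limitations

* The gene-score model is the SNP-wise sum statistic only; competitive
  gene-set regression and top-SNP variants are not implemented.
* LD clumping and gene-score LD use the synthetic generator's known
  structure or empirical dosage correlations — there is no external
  reference panel.
* Single-causal-variant fine-mapping and coloc assume at most one
  signal per region per trait.
* The pipeline's permutation and overlap statistics inherit the small
  demo scale; their published-scale behavior is validated through the
  desk-reproducible overlap statistic and the calibration properties,
  not by reproducing cohort-dependent counts.
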