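# pgnet

Proteogenomic network analysis for case/control traits: a three-phase
pipeline that links disease GWAS signals to plasma-protein regulation
and nominates candidate effector proteins by converging evidence.

The package is aimed at statistical geneticists and systems biologists
who want to exercise, test, and extend this class of analysis without
access to biobank-scale individual-level data: a first-class synthetic
cohort generator reproduces the statistical structure every stage
assumes (LD-blocked genotypes, a liability-threshold trait, a protein
panel with cis/trans genetic effects, a scale-free PPI network with a
planted disease module), so the whole pipeline runs end to end in
seconds and every estimator can be checked against planted truth.

## What it computes

**Phase 1 — proteogenomics.** Per-variant QC (MAF, call rate, exact
Hardy-Weinberg test), covariate-adjusted logistic association with a
Firth fallback under separation, fixed-effects inverse-variance
meta-analysis of two cohorts (β̂ = Σwᵢβᵢ/Σwᵢ, wᵢ = 1/SEᵢ², with allele
harmonization), pQTL mapping of a protein panel (OLS with the
age/age²/sex interaction design; p kept as −log₁₀p to survive extreme
association strengths), cis/trans classification, and the
GWAS-hit × pQTL intersection.

**Phase 2 — network analysis.** SNP p-values collapse to gene scores
via the chi-square sum statistic T = Σⱼ[Φ⁻¹(1−pⱼ/2)]², whose null is
the weighted sum Σλᵢχ²₁ over eigenvalues of the local LD matrix
(computed exactly by Imhof inversion with a saddlepoint tail).  Gene
z-scores weight the PPI nodes, and a greedy dmGWAS-style search grows
one module per seed: candidates within graph distance d = 2 are added
while the module score Zm = Σz/√k improves by more than the factor
(1 + r), r = 0.1.  Modules are normalized against random same-size
node sets (Zn), the top 1% is selected, and overlap of the selected
proteins with pQTL proteins is tested by one-sided Fisher.  A
hypothesis-driven branch extracts first-degree neighbors of risk loci
and assesses pQTL-protein enrichment with a 10,000-iteration
permutation test.

**Phase 3 — causal inference and triangulation.** Cis-pQTL
instruments (LD-clumped at r² < 0.001, allele-harmonized) feed
two-sample MR — Wald ratio for single instruments, fixed-effect IVW,
weighted median with bootstrap SE — with BH FDR and a
simulation-based global horizontal-pleiotropy screen.  Regional
colocalization uses Wakefield approximate Bayes factors with the
H0–H4 decomposition (priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵); fine-mapping
uses the single-causal-variant ABF posterior and 95% credible sets.
Evidence is triangulated across the pQTL, top-module, and
neighborhood target sets; variant-to-distal-gene links are mapped
through chromatin-loop anchors.

## Worked example

The numbered drivers under `analysis/` run the demo study
(configuration in `analysis/config.yaml`; everything lands in
`results/pipeline_run/`):

```bash
cd analysis
python 01_simulate_cohorts.py
python 02_gwas_and_meta.py
python 05_dense_modules.py
python 07_mr_coloc_finemap.py
```

prints (seed 1):

```
cohort A: 2000 samples, 240 variants in 12 LD blocks, 238 cases
...
meta-analysis: 224 shared variants after harmonization
genome-wide significant (p < 5e-8): 9 variants
top signal: v00143 beta=0.926 p=2.24e-32
...
300 modules searched; top 1% = 3 modules covering 27 proteins
...
MR: 18 proteins tested, 4 at FDR < 0.05
  G0299 [Wald ratio] beta=-1.676 fdr=4.04e-31
```

Nine of the 240 variants reach genome-wide significance in the
meta-analysis (the generator planted 8 causal variants, some in LD
with neighbors); four proteins carry significant MR evidence of a
causal abundance-disease link, all of them proteins whose cis variant
was planted on a disease-causal site — the mediation chain the
pipeline is designed to recover.  The same ten stages run from a
single command: `pgnet run --config analysis/config.yaml`.

Library usage mirrors the drivers:

```python
from pgnet.synthetic import CohortSpec, simulate_cohort
from pgnet import assoc, netmod

cohort = simulate_cohort(CohortSpec(seed=1))
gwas = assoc.gwas_scan(cohort.genotypes, cohort.variant_table,
                       cohort.phenotype, cohort.covariates)
```

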