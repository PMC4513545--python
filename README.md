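# liabkit

SNP-heritability analysis for ascertained case-control cohorts under the
liability threshold model. The package implements the full pipeline used in
GWAS heritability studies of rare diseases:

- **io_formats** — PLINK BED/BIM/FAM (SNP-major), GCTA binary GRM triplets,
  BED annotation intervals, whitespace-delimited phenotype tables.
- **qc** — Hardy-Weinberg exact test (controls only), call-rate and MAF
  filters, IBS-based relatedness pruning, genomic inflation factor λ_GC.
- **grm** — realized genetic relationship matrices (pairwise-complete over
  missing genotypes, GCTA-style companion diagonal estimator), risk-locus
  window subsets, and the incomplete-LD adjustment sweep.
- **greml** — AI-REML variance components (EM warm-up, step-halving, floor
  constraints or unconstrained) for one or many GRMs, a fast single-GRM
  eigendecomposition path, the observed→liability conversion with
  ascertainment correction, and the per-SNP covariate-difference procedure.
- **pcgc** — phenotype-correlation genotype-correlation regression with the
  analytic ascertainment correction and a sample-block jackknife SE.
- **liability** — closed-form calculus: scale-conversion factor
  K²(1−K)²/(z²P(1−P)), recurrence risk via the bivariate-normal orthant
  probability, fraction of familial risk explained, and a log-normal
  polygenic-risk-score model for top-percentile risk.
- **partition** — per-chromosome joint fits with the chromosome-length
  regression, risk-locus vs remainder two-GRM fits, annotation
  (transcript/non-transcript) splits, and subtype-stratified estimates.
- **synthetic_data** — reproducible ascertained cohorts: HWE genotypes with
  optional block LD, liability phenotypes with designated large-effect risk
  SNPs, exact rejection-sampling ascertainment, subtype labels. Seeded
  through counter-based Philox streams.
- **pipeline / cli** — end-to-end orchestration with a JSON report.

## Command line

```bash
liabkit simulate --config sim.yaml --seed 1 --out cohort     # PLINK + pheno + truth
liabkit qc --bfile cohort --pheno cohort.pheno --out clean
liabkit grm --bfile clean --out g                            # GCTA GRM triplet
liabkit reml --grm g --pheno cohort.pheno -k 0.00739
liabkit pcgc --grm g --pheno cohort.pheno -k 0.00739
liabkit partition chrom --bfile clean --pheno cohort.pheno -k 0.00739
liabkit partition loci  --bfile clean --pheno cohort.pheno -k 0.00739 --locus 3:1500000
liabkit partition annot --bfile clean --pheno cohort.pheno -k 0.00739 --bed transcripts.bed
liabkit liability transform --h2-obs 0.25 -k 0.00739 -p 0.305
liabkit liability familial-fraction --h2 0.152 -k 0.00739 --lambda-obs 2.45
liabkit liability prs --target-rr 6.29 -k 0.00739
liabkit reproduce --scale 0.3 --seed 0 --out results/       # whole synthetic pipeline
```

`liabkit reproduce` runs QC → GRM → GREML + PCGC → LD sweep → partitions →
familial-risk and PRS calculus on a synthetic cohort scaled down from a
~2,282-case / ~5,197-control design (lifetime risk K = 0.00739, case fraction
0.305), and writes `report.json` plus TSV tables.

## Notes

- Case-control phenotypes are analysed as 0/1 on the observed scale (linear
  mixed model) and converted to the liability scale post hoc; PCGC provides
  the ascertainment-robust alternative on the same GRM.
- The REML fitter is deterministic; all stochasticity lives in simulation
  seeds. Multi-component fits expose `RemlSettings(allow_negative=True)` for
  unconstrained estimation (useful for difference-based per-SNP estimates).
- Simulation studies in `liabkit.replication` are desk-scaled; tolerances are
  phrased in Monte-Carlo SEs so they adapt to the chosen scale.
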