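# ssgp — single-step genomic prediction toolkit

Single-trait genomic prediction of breeding values combining genotyped and
non-genotyped relatives:

- **Pedigree machinery** — numerator relationship matrix `A` (tabular method),
  inbreeding, and the `A_gg / A_ng / A_nn` partitions used by single-step models.
- **Genotype machinery** — marker QC (missing rate, MAF, Hardy–Weinberg),
  mean imputation of sporadic missing calls, the centered genomic relationship
  matrix `G = TT'/Σ2q(1−q)`, mean-matching of `G` to `A_gg`, SNP-effect
  reweighting of `G`, pedigree-vs-genomic conflict detection (duplicate
  samples, parentage errors), and imputation of SNP covariates for
  non-genotyped animals (`M̂_n = A_ng A_gg⁻¹ M_g`).
- **Mixed models** — Henderson mixed-model solutions, PBLUP / PBLUP-G, the
  combined relationship matrix `H`, and SSGBLUP I/II/III (standard and
  iteratively reweighted `G`), with Gibbs-sampled variance components.
- **Bayesian whole-genome regression** — BayesB / BayesC / BayesCπ Gibbs
  samplers (spike-and-slab priors, numba-compiled locus sweeps) and their
  single-step extensions SSBR-B / SSBR-C / SSBR-Cπ with imputed covariates,
  imputation residuals `ε`, and the genotyped-status shift `μ_g`.
- **Evaluation** — K-means cross-validation folds on relationship profiles,
  phenotype pre-adjustment, accuracy (`cor/√h²`), size-weighted pooling, and
  bias (regression of phenotype on EBV).
- **GWAS** — proportion of genetic variance per 1-Mb window from posterior
  marker-effect draws.
- **Synthetic data** — multi-generation pedigrees, gene-dropped genotypes,
  polygenic or major-QTL traits, genotyping masks, and planted data errors,
  so every stage is testable without external data.

## Python API sketch

```python
import ssgp

cfg = ssgp.SimConfig(n_founders=100, n_generations=4, matings_per_generation=75,
                     offspring_per_mating=2, n_snps=500, h2=0.5, seed=7,
                     genotyped_generations=frozenset({3, 4}))
bundle = ssgp.simulate_all(cfg)

A = ssgp.build_nrm(bundle.pedigree)
part = ssgp.partition_nrm(A, bundle.genotypes.animal_ids)
G = ssgp.scale_grm(ssgp.build_grm(bundle.genotypes), part.A_gg)

vc = ssgp.VarianceComponents.from_h2(0.5, var_y=float(bundle.phenotypes.y.var()))
fit = ssgp.fit_ssgblup(bundle.phenotypes, part, G, vc, variant="I")

design = ssgp.build_ssbr_design(part, bundle.genotypes)
post = ssgp.fit_ssbr(bundle.phenotypes, design,
                     ssgp.PriorSpec(family="B", pi=0.95), vc,
                     ssgp.McmcSettings(n_iter=20_000, burn_in=5_000, thin=5, seed=1))
```

## Command line

```bash
ssgp simulate --config sim.yaml --out data/
ssgp qc --geno data/genotypes.raw --out qc/
ssgp conflicts --geno qc/genotypes_qc.raw --pedigree data/pedigree.csv --out conflicts.csv
ssgp fit --method ssgblup1 --pedigree data/pedigree.csv --pheno data/phenotypes.csv \
         --geno qc/genotypes_qc.raw --out ebv.csv
ssgp cv --methods pblup,bayesc,ssgblup1,ssbr-c --k 5 --h2 0.5 \
        --pedigree data/pedigree.csv --pheno data/phenotypes.csv \
        --geno qc/genotypes_qc.raw --out report.csv
ssgp gwas --pheno data/phenotypes.csv --geno qc/genotypes_qc.raw \
          --map data/map.csv --pi 0.95 --out windows.csv
ssgp pipeline --config run.yaml
```

File formats are plain text: pedigree CSV (`id,sire,dam[,generation]`, 0 =
unknown parent), whitespace-delimited genotype matrix with a marker header
(0/1/2 codes, `NA` missing), marker map CSV (`marker,chrom,pos_bp`),
phenotype CSV (`id,value[,cg,age]`).

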