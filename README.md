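# ciseqtl

Cis-eQTL refinement at GWAS susceptibility loci, as a tested, reusable
pipeline:

* **robust covariate adjustment** — each expression trait is residualized on
  age, sex and smoking status by Huber M-estimation (IRLS, c = 1.345, MAD
  scale), then residuals deviating from their median by more than three
  sample standard deviations are masked as outliers;
* **per-locus association scans** — every SNP in a locus window is tested
  against every locus probeset by simple linear regression of the adjusted
  residual on allele dosage, with two-sided Wald t-tests (n − 2 df) and
  per-test variance explained (r²);
* **multiple-testing thresholds** — the spectral effective number of
  independent tests (Meff = Σ [I(λ ≥ 1) + (λ − ⌊λ⌋)] over correlation-matrix
  eigenvalues) is computed separately for the SNP and probeset dimensions,
  giving a composite per-locus Bonferroni threshold α/(Meff_SNP × Meff_probe);
* **LD linkage** — significant eQTL-SNPs are connected to the GWAS SNPs by
  dosage-correlation r² (linked if r² > 0.5 by default); GWAS SNPs absent
  from the panel are reported as not genotyped;
* **two-cohort replication** — discovery-significant eQTLs are classified as
  discovery-only / replicated in one / replicated in both replication
  cohorts at nominal p < 0.05, with slope-direction consistency recorded;
* **a study simulator** — multi-cohort genotype/covariate/expression data
  with haplotype-pool LD blocks, covariate effects, planted cis-eQTLs of
  configurable variance explained, injected expression outliers, and a
  ground-truth table, fully deterministic under a seed.

## Command line

```sh
# generate a synthetic 3-cohort study plus a ready-to-run config
ciseqtl simulate --seed 7 --outdir study/

# full pipeline: adjust, scan, thresholds, replication, LD linkage
ciseqtl run --config study/pipeline_config.yaml --outdir reports/

# individual stages
ciseqtl adjust --expression expr.tsv --covariates cov.tsv --out residuals.tsv
ciseqtl scan --vcf cohort.vcf --residuals residuals.tsv --locus loci.yaml --out results.tsv
ciseqtl meff --vcf cohort.vcf --residuals residuals.tsv
ciseqtl ld --vcf cohort.vcf --out ld_matrix.tsv
ciseqtl replicate --discovery disc.tsv --replication u rep_u.tsv \
    --replication g rep_g.tsv --threshold 5.1e-6 --out replication.tsv
```

`run` writes, per locus: the full and significant eQTL tables, the
threshold report (raw and effective test counts, composite threshold),
the replication report, the LD-linkage table, per-eQTL boxplot data and a
JSON run log with per-stage counts. Reruns with the same config are
byte-identical. Exit codes: 0 success, 2 input error, 3 computation error.

### File formats

Genotypes are VCF 4.x (biallelic, GT fields; dosage counts the alt
allele, missing genotypes allowed). Expression is a TSV with rows
`probeset_id, gene, <sample columns>`; covariates a TSV with columns
`sample_id, age, sex, smoking`. Locus definitions are YAML (name,
chromosome, GWAS SNPs with 1-based positions, gene list); windows are
built as ±1 Mb (configurable) around the most distant GWAS SNPs. All
coordinates are 1-based inclusive internally; BED locus input is
converted at the boundary.

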