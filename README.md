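# proxymr

Mendelian randomisation (MR) with family-proxy outcomes, end to end and on
plain-text formats:

- **`proxymr.cohort`** — simulation of nuclear families (father, mother, index
  offspring, 0–3 siblings) with Mendelian haplotype transmission, block LD,
  three correlated standardised lipid-like exposures, liability-threshold
  diseases and a linear lifespan model assigned to each relative from their
  *own* genotype, plus self-report misclassification and any-affected sibling
  aggregation. Because relatives share half their alleles with the index
  individual, per-allele outcome effects estimated against offspring dosage
  are diluted by an expected factor of two — the core property the package is
  built to study.
- **`proxymr.instruments`** — inverse rank-normalisation (Blom offset),
  per-SNP OLS GWAS (quantitative and linear-probability binary, with the
  μ(1−μ) log-odds rescaling), greedy LD clumping against a reference panel
  (p < 5×10⁻⁸, r² < 0.001, 1 Mb window by default), pooled multivariable
  clumping, mean and conditional F-statistics, and region exclusion.
- **`proxymr.estimators`** — allele harmonisation (strand flips, palindromic
  SNPs resolved by allele frequency), Wald ratio, IVW, MR-Egger, weighted
  median, weighted mode, multivariable IVW and multivariable MR-Egger, with
  multiplicative random-effects standard errors and seeded bootstrap SEs.
- **`proxymr.screen`** — the 38-slot first-degree-relative outcome catalogue,
  Benjamini–Hochberg FDR screening, sensitivity suites, bidirectional MR,
  mediation proportions, dilution ratios, years→months reporting and
  sex-stratified re-estimation.
- **`proxymr.io` / `proxymr.cli`** — TSV formats, validated YAML config, and
  the `proxymr` command line.

## Command line

```sh
# simulate a cohort (genotype dosage text + SNP metadata + phenotype TSV)
proxymr simulate --seed 1 --n-families 2000 --n-snps 150 --out scratch/cohort

# per-SNP GWAS of one offspring trait
proxymr gwas --genotypes scratch/cohort/cohort \
             --phenotypes scratch/cohort/phenotypes.tsv \
             --trait apoB --out scratch/apob.tsv

# LD clumping (one file = univariable; several = pooled multivariable)
proxymr clump --stats scratch/apob.tsv --panel scratch/cohort/cohort \
              --p-thresh 5e-8 --r2 0.001 --window 1000000 \
              --out scratch/instrument.tsv

# MR (multivariable when several --exposure files are given)
proxymr mr --exposure scratch/instrument.tsv --outcome scratch/outcome.tsv \
           --methods ivw,egger,wmedian,wmode --out scratch/mr.tsv

# the whole thing from one config
proxymr pipeline --config examples/toy.yaml --out scratch/run
```

The pipeline writes `screen.tsv`, `sensitivity.tsv`, `mediation.tsv`,
`forest_data.tsv`, `instrument_strength.tsv` and a `run.log` (seed, version,
config hash). Runs are byte-identical under a fixed seed: all randomness
flows from the config seed through named substreams.

## Summary-statistics format

Tab-separated with header
`SNP chr pos effect_allele other_allele eaf beta se pval n trait scale`;
`.` marks a missing effect-allele frequency; `scale` is one of `sd-units`,
`log-odds`, `years`, `linear-probability`.
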