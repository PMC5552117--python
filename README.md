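# allelichrom

Allele-specific chromatin analysis for F1-hybrid ChIP-seq/RNA-seq-style
data: allelic fragment assignment and region counting, allelic-skew
calling with exact binomial tests and Benjamini–Hochberg FDR control,
silent/bivalent/active chromatin-state classification, and Bayes-factor
prediction of allelic expression skew. A seeded synthetic-data
generator emulates the statistical structure of clonal hybrid
fibroblast data (two alleles per gene, three gross chromatin states,
continuous within-state allelic skew, ~37% ChIP / ~17% RNA allelic
read fractions, expression driven log-linearly by allelic mark
densities) and ships a ground-truth table for recovery testing.

## Package layout

| module | role |
| --- | --- |
| `allelichrom.synthetic` | seeded generator: annotation, allelic states/densities, count tables, fragment BEDs, truth table |
| `allelichrom.coverage` | allelic assignment from per-haplotype scores, dedup, promoter (TSS ± 1 kb) / gene-body counting, input-normalized and inferred allelic densities, per-chromosome balance |
| `allelichrom.skew` | exact two-sided binomial skew test, BH FDR, log2 mus:cas ratios, the ≥15-reads / >2-fold / FDR<0.05 caller, set summaries, hypergeometric overlap, hybrid-vs-inbred concordance |
| `allelichrom.states` | silent/bivalent/active classification in K4me3/K27me3 density space, data-driven threshold fitting, allelic state-pair census, cross-mark skew correlations, per-state skew distributions |
| `allelichrom.prediction` | train/validation split, per-assay expressed/non-expressed KDE references, summed log Bayes factors per allele, linear CV models, variance decomposition, ROC over skew cutoffs, qPCR fold utility |
| `allelichrom.io` / `allelichrom.cli` / `allelichrom.pipeline` | TSV/BED readers and writers with validation, YAML run config, deterministic manifests, CLI |

## CLI

```sh
allelichrom simulate --seed 1 --n-genes 2000 --outdir run/
allelichrom call-skew --counts run/counts_K4me3.tsv --assay K4me3 --out run/skew_K4me3.tsv
allelichrom classify --countsdir run/ --out run/states.tsv
allelichrom census --states run/states.tsv --out run/census.tsv
allelichrom predict --countsdir run/ --outdir run/pred/
allelichrom evaluate --countsdir run/ --outdir run/eval/
allelichrom report --rundir run/
```

All tables are TSV with headers; fragment intervals are 0-based
half-open BED (per-haplotype alignment scores in columns 7–8, or a
pre-assigned allele label in column 4). Each output directory carries
a `manifest.json` with content hashes and the effective config; no
timestamps, so identical configs and seeds reproduce every output byte
for byte. Note the fitted state-region boundaries are a data-driven
reconstruction, not measured constants.

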