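# rnasomatic

Somatic mutation discovery and significance analysis for paired tumor/normal
RNA-Seq, built as a reusable, tested pipeline:

- **Three-filter somatic cascade** (`variant_filters`): QUAL ≥ 20 / ≥ 2
  supporting reads / read depth in [3, 500]; paired-coverage screening
  (position covered at depth ≥ 3 in both members of a pair); subtraction of
  pair-shared and blacklisted (dbSNP-style) variants — with a per-stage
  attrition report.
- **Mutation spectrum & background rates** (`mutation_spectrum`): six base
  categories (A, T, C/G in and out of CpG context), seven mutation categories
  (AT/CpG/CG transitions and transversions plus indels), per-sample
  background mutation rates over covered (depth ≥ 3) bases.
- **Significantly mutated genes** (`smg`): per-category binomial tail
  probabilities combined by Fisher's combined P-value test (χ², df = 2 ×
  categories); consensus calling (eligible genes with P < 0.01 in every
  tumor and in no normal); SMG-vs-other mutation-rate comparison.
- **Disruptive genes** (`consequence`): codon-level consequence annotation;
  tumor-specific disruptive genes (nonsynonymous/indel variants in every
  tumor, none in any normal).
- **Differential expression** (`expression`): median-of-ratios size factors,
  pooled-dispersion negative-binomial exact test, Benjamini–Hochberg.
- **Enrichment** (`enrichment`): hypergeometric over-representation against
  GMT category maps; gene-set overlap tests.
- **Synthetic cohorts** (`synthetic_data`): seeded paired tumor/normal
  simulator with planted SMG/TDG/DEG truth labels, used throughout the test
  suite.
- **Orchestration** (`pipeline`, `cli`): config-driven end-to-end runs with
  manifests and a Table-2-style consolidated report.

## CLI

Simulate a synthetic fixture cohort and run the full pipeline on it:

```bash
oscc-pipeline simulate --seed 1 --out fixtures/ --genes 60
cat > fixtures/run.cfg <<EOF
fasta=transcripts.fa
annotation=transcripts.bed
blacklist=blacklist.vcf
counts=counts.tsv
out=results
sample=P1N,normal,P1,P1N.vcf,P1N.depth.tsv
sample=P1T,tumor,P1,P1T.vcf,P1T.depth.tsv
sample=P2N,normal,P2,P2N.vcf,P2N.depth.tsv
sample=P2T,tumor,P2,P2T.vcf,P2T.depth.tsv
EOF
oscc-pipeline run --config fixtures/run.cfg
```

Run just the cascade on one matched pair:

```bash
somatic-cascade --normal a.vcf --tumor b.vcf \
    --normal-depth a.depth.tsv --tumor-depth b.depth.tsv \
    --blacklist dbsnp.vcf --report report.tsv
```

Inputs are plain-text VCFv4.2 (INFO/DP, INFO/AD), 3-column depth TSVs
(chrom, 0-based pos, depth), FASTA + BED12/GFF3 transcript models, a
gene × sample counts TSV and GMT category maps.

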