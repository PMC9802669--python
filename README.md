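# methexp

Methylome–transcriptome comparative analysis as a reusable, tested pipeline:

- **synthetic data** — genomes, gene models, per-cytosine bisulfite reports,
  and negative-binomial count matrices with *planted* DMRs, DEGs,
  promoter-methylation ↔ expression anti-correlation, and co-expression
  modules, so every downstream stage can be scored against ground truth;
- **methylome** — CG/CHG/CHH context assignment from the genome, binomial-test
  methylcytosine calling (coverage ≥ 4 in all compared samples, P < 1e-4),
  per-context levels / mC fractions, and 1 Mb / 200 kb sliding-window tracks;
- **dmr** — differentially methylated regions between two samples: windows of
  ≥ 5 same-context sites, pooled-level difference > 0.1, two-sided Fisher
  exact P ≤ 0.05, with interdependent nearby regions merged when the spanning
  region still passes both criteria;
- **expression** — FPKM (`1e9·C/(N·L)`), differential expression (fold change
  ≥ 2, BH-adjusted P ≤ 0.001, FPKM ≥ 1 in ≥ 1 sample), K-means clustering of
  z-scored log2 profiles, sample dendrogram and PCA;
- **coexpression** — unsigned soft-threshold adjacency (`|r|^β`, β = 6),
  topological overlap matrix, and neighbour selection around seed genes at
  similarity ≥ 0.2;
- **integration** — DMR–gene association over "body + 2 kb upstream",
  DEG enrichment among DMR-associated genes (fold + hypergeometric tail),
  hyper/hypo × up/down cross-tabs, genome-wide window-level
  methylation–expression correlation, and flat term enrichment.

## Command line

Every stage is a subcommand of `methexp`; stages exchange plain-text files
under one output directory and a manifest records checksums and row counts.

```sh
methexp --config config.yaml --outdir out all        # whole pipeline
methexp --config config.yaml --outdir out simulate   # or stage by stage:
methexp --config config.yaml --outdir out callmc
methexp --config config.yaml --outdir out dmr
methexp --config config.yaml --outdir out deg
methexp --config config.yaml --outdir out cluster
methexp --config config.yaml --outdir out network
methexp --config config.yaml --outdir out integrate
```

A minimal `config.yaml` (all thresholds default to the published rule set;
omitted keys keep their defaults):

```yaml
seed: 1
simulation:
  n_chromosomes: 2
  chrom_length: 500000
  n_genes: 100
  n_replicates: 3
  anticorrelation_fraction: 0.2
  n_modules: 1
params:
  window: 100000   # sliding-window size for tracks/correlation
  step: 20000
```

Exit codes: `0` ok, `2` config error, `3` missing input, `4` runtime failure.
Reruns with the same config and seed are byte-identical.

## Formats

- genome: FASTA; genes: GFF3 (1-based, feature `gene`) and BED6;
- cytosine reports: 6-column TSV `chrom pos strand count_methylated
  count_unmethylated context` (1-based, strand-resolved);
- counts: genes × samples TSV with a companion gene-length TSV and a sample
  sheet `sample_id genotype stage replicate`;
- DMRs: BED-like TSV (0-based half-open) with pooled levels, difference,
  Fisher P, direction, and merge count;
- window tracks: bedGraph / TSV; annotations: 2-column `gene_id term_id` TSV.
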