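# ddradkit

Design and diagnostics toolkit for double-digest RAD-seq (ddRAD-seq)
genotyping platforms: in silico double digestion and enzyme-pair ranking,
sequencing yield/depth planning, coverage-overlap diagnostics for multiplexed
libraries, and variant-set summaries — all exercisable on seeded synthetic
data with planted ground truth.

## Modules

| Module                | What it does |
| --------------------- | ------------ |
| `ddradkit.digestion`  | Single/double restriction digestion of a genome, fragment end classification (AB+BA / AA / BB / chromosome-end), inclusive size windows, enzyme-pair ranking by windowed AB+BA count. Ships REBASE definitions for PstI, MboI, MspI, EcoRI, SphI, ApeKI; user tables can override. |
| `ddradkit.design`     | Target-bp range (`n_loci x window`), expected fold-coverage at a given per-sample yield, yield↔read-pair conversion under both base-counting conventions. |
| `ddradkit.coverage`   | Breadth/depth summaries (per sample and merged), 1000-bp bin count matrices, Spearman/Pearson sample correlation with average-linkage clustering order, PCA of log1p bin counts, per-pool common covered sites, and the experimental-vs-artificial pool comparison (paired t-test). |
| `ddradkit.variants`   | SSR scan with MISA-style thresholds (mono >= 10 units, di >= 6, tri..hexa >= 5; interrupted runs merge into imperfect SSRs), InDel SSR classification via flank embedding, Ts/Tv, per-alt-allele deletion/insertion stats, sharing distribution, strict-missingness / inclusive-MAF filtering, rate summaries, per-window density. |
| `ddradkit.synthetic`  | Seeded generators for genomes (planted restriction sites, site-free centromere-like spans, an oversampled organellar-homolog hotspot, SSR tracts), per-sample alignments (gamma-distributed yields at a configurable CV, pool-level size-window shifts) and genotype matrices (Hardy-Weinberg at known MAF, configurable missingness) — each with truth tables. |
| `ddradkit.cli_io`     | FASTA/SAM/VCF/TSV readers and writers, pipeline configuration, the `ddrad` CLI. |

## CLI

```bash
ddrad simulate --seed 7 --out sim/            # synthetic dataset + truth tables
ddrad digest --fasta sim/genome.fa --enzymes PstI,MboI --window 300:400 --out dg
ddrad rank --fasta sim/genome.fa --pairs PstI/MboI,SphI/MspI --window 300:400
ddrad plan --n-loci 63730 --window 300:400 --yield 250e6
ddrad covstats --alignments sim/alignments.tsv
ddrad bins --alignments sim/alignments.tsv --bin-size 1000
ddrad corr --alignments sim/alignments.tsv
ddrad pca --alignments sim/alignments.tsv
ddrad common-sites --alignments sim/alignments.tsv --pool-map sim/pools.tsv
ddrad artificial-pools --alignments sim/alignments.tsv --pool-map sim/pools.tsv --k 3 --seed 7
ddrad ssr --fasta sim/genome.fa
ddrad tstv --vcf sim/variants.vcf
ddrad indel-stats --vcf sim/variants.vcf
ddrad sharing --vcf sim/variants.vcf
ddrad filter --vcf sim/variants.vcf --max-missing 0.05 --min-maf 0.01
ddrad density --vcf sim/variants.vcf --window 1000
ddrad run --genome sim/genome.fa --alignments sim/alignments.tsv \
          --vcf sim/variants.vcf --pool-map sim/pools.tsv --out out/
```

Alignments are accepted as coordinate-sorted SAM/BAM (MAPQ > 3 kept, as in
the alignment step the pipeline consumes) or as a plain 4-column interval TSV
(`sample  chrom  start  end`, 0-based half-open).

## Conventions

- Coordinates are 0-based half-open; a cut position is a between-base index;
  size windows are inclusive on both ends.
- Read mates are counted as independent segments in all coverage analyses;
  a segment belongs to the bin containing its leftmost aligned base.
- Missingness filtering is strict (`<`), MAF filtering inclusive (`>=`);
  multiallelic MAF defaults to the second-most-frequent-allele convention.
- Methylation sensitivity of enzymes is metadata only; digestion does not
  model it.
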