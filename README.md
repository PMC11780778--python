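# equase

Haplotype-resolved allele-specific expression (ASE) analysis. Starting from
phased heterozygous loci (long-read phasing output) and per-locus read
counts (samtools `mpileup` text), `equase`:

1. **tallies** the nucleotides observed at each heterozygous position
   (`equase.pileup`),
2. **aggregates** per-locus counts into the two haplotype expression values
   of each phased block (`equase.haplotypes`),
3. **calls** allelic imbalance with a log2 allele-expression fold change
   (aeFC), an exact two-sided binomial test and Benjamini–Hochberg FDR
   control, under the criteria |aeFC| ≥ 2, adjusted p ≤ 0.05, max allele
   expression ≥ 5, after a coverage ≥ 10 filter (`equase.stats`),
4. **annotates** events with VEP variant consequences (dropping loci that
   are exclusively intronic/intergenic) and with histone-mark peak overlap
   (H3K27ac, H3K4me1, H3K4me3, H3K27me3) over the region spanned by each
   block's het loci (`equase.annotation`),
5. **replicates** discovery loci in an independent cohort with direction
   concordance, per-locus replication frequency and a one-way ANOVA with
   eta-squared (`equase.validation`).

A synthetic-data generator (`equase.simulate`) produces cohorts with known
ground truth in exactly the input formats the pipeline reads, for
calibration and parameter-recovery experiments.

## CLI

```sh
# synthetic cohort with ground truth
equase simulate --seed 7 --n-genes 100 --prop-ase 0.2 --out sim/

# discovery: count, aggregate, test, annotate
equase call --haplotypes sim/haplotypes.tsv --pileup-dir sim/ \
    --peaks sim/peaks.bed --vep sim/consequences.tsv \
    --coverage-min 10 --aefc 2 --alpha 0.05 --min-expr 5 \
    --fdr-family sample_tissue --out out/

# per-tissue summary of a resource table
equase summarize --resource out/resource.tsv --out tissue_summary.tsv

# consequence filtering / variant-type summary on its own
equase annotate --vep sim/consequences.tsv --out anno/

# replication in an independent cohort
equase validate --discovery-loci out/discovery_loci.tsv \
    --samples samples.tsv --out val/
```

`equase call` writes the master resource table (`resource.tsv`), per-tissue
subsets, the per-locus favored-allele table for validation
(`discovery_loci.tsv`), the removed intronic/intergenic loci sidecar, and a
`manifest.json` with input checksums, the config snapshot, stage timings
and filter-chain counts. `equase validate` consumes a tab-delimited sample
sheet with `sample_id`, `group` and `mpileup` columns and writes the
comparison table plus a concordance summary.

### Input formats

- **Haplotype table** (TSV): `sample`, `tissue`, `haplotype_block_id`,
  `chrom`, `pos` (1-based), `allele_h1`, `allele_h2`. Blocks on sex
  chromosomes are dropped unless `--keep-sex-chromosomes` is given.
- **Pileup**: single-sample samtools `mpileup` text (plain or gzip); with
  `--pileup-dir`, files are named `<sample>.<tissue>.mpileup`.
- **Peaks**: BED3+ (0-based half-open, converted on read) with mark,
  tissue and sample labels in columns 4–6, or supplied to the reader.
- **Consequences**: VEP tab-delimited output (`Location`, `Gene`,
  `Consequence`, optionally `SYMBOL`); rows per locus are merged by union
  of terms.

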