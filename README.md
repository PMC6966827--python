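# splicestress

Statistics for characterizing stress/infection-induced alternative-splicing
changes, built as a reusable, tested pipeline with a synthetic-data module
that plants parameterized effects so every stage is verifiable by parameter
recovery — no external downloads required.

## What it does

| Module | Contents |
| --- | --- |
| `splicestress.synthetic` | Simulated gene/isoform annotations, Dirichlet isoform-ratio tables with a planted condition effect, binomial intron-retention counts with planted delta-PSI, variant tables with a realistic allele-frequency spectrum and planted positional bias, hexamer-planted sequences, and uORF intervals with planted overlap enrichment. Truth tables are always written alongside the data. |
| `splicestress.diversity` | Isoform read filtering (>1 read in ≥90% of samples), Shannon-entropy diversity and per-line net entropy shifts, and a permutation multivariate distance test on isoform-ratio vectors (pseudo-F/R² statistic, dispersion-homogeneity check, BH adjustment). |
| `splicestress.efflen` | Ratio-weighted effective lengths of transcripts and features (5'UTR/CDS/3'UTR, plus transcript-minus-feature variants), increase/decrease/unchanged classification against a sample-shuffling permutation null with repeated G-tests (df = 2, Bonferroni), and 3'UTR mechanism classification (Splicing vs alternate polyadenylation vs ambiguous). |
| `splicestress.sqtl` | Strand-aware metagene and intron-relative variant positioning, allele-frequency-matched null variant resampling (exact per-bin counts), exact overlapping hexamer scanning, and element-overlap enrichment (z against the null sets). |
| `splicestress.retention` | Beta-posterior PSI estimation from retention/splicing read counts, Savage–Dickey Bayes factors for delta PSI (significant: BF > 10 and \|dPSI\| > 0.2), cross-line recurrence tables, and expected multi-set overlap with a simulated p-value. |
| `splicestress.characterize` | GC content (with intron-minus-flank differences), one-tailed Welch comparisons (log2 option for lengths), RPKM → quantile normalization → per-event triplet standardization for ChIP signal, and the paired logit t-test for uORF overlap of increased- vs decreased-retention introns. |

## CLI

All stages are exposed under one entry point:

```sh
# generate all synthetic inputs (+ truth tables + schema.json)
splicestress simulate --config cfg.yaml --outdir sim/ --seed 1

# distance test + entropy shift summaries
splicestress diversity --ratios sim/ratios.tsv --out div/ --n-perm 10000

# effective-length change classification with the permutation G-test
splicestress efflen --ratios sim/ratios.tsv --lengths sim/lengths.tsv --out el/

# element-overlap enrichment of sQTLs vs AF-matched nulls
splicestress sqtl-pos --variants sim/variants.tsv --seqs sim/sequences.fa \
    --genes genes.tsv --motifs sim/motifs.txt --out sq/

# Bayes-factor delta-PSI calls and cross-line recurrence
splicestress retention --counts sim/retention_counts.tsv --out ret/ --recurrence-k 4

# uORF overlap comparison
splicestress characterize --introns introns.tsv --uorfs sim/uorfs.bed --out ch/
```

The `cfg.yaml` file holds any `SimConfig` fields (see
`splicestress/config.py`); every file format is plain text and documented in
the `schema.json` written next to the simulated data.

## Conventions

- Coordinates are 0-based, half-open; minus-strand genes store features in
  transcription order (index 0 = 5' end).
- Entropy is in nats; delta quantities are infected − control throughout.
- All randomness flows through explicit `numpy.random.Generator` objects;
  the simulator is byte-deterministic given its config seed.
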