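# coculture

Analysis toolkit for pairwise co-culture interaction experiments in small
bacterial communities (e.g. a four-strain *Streptomyces* community). It
implements, as a tested reusable pipeline:

- **`coculture.synthdata`** — generators for every input the pipeline
  consumes, with planted ground truth: toy strain genomes with shared genes
  and embedded rRNA, RNA-seq reads (optionally multiplexed) whose names
  encode their true origin, LC-MS peak tables with injection-order drift,
  batch shifts, QC injections and intensity-dependent missingness, plate
  images with disk colonies and a rim of known diameter, and gene→KO→pathway
  maps.
- **`coculture.rnaseq`** — deconvolution of (multiplexed) RNA-seq libraries
  by competitive k-mer assignment against concatenated strain genomes:
  k-mer rRNA decontamination, per-strain scoring with strict-tie AMBIGUOUS
  discard, anchor-based gene counting, median-of-ratios size factors, TPM,
  a simplified negative-binomial differential-expression test (Wald and
  partner×day LRT modes), and a multiplexing-fidelity check.
- **`coculture.metabolomics`** — peak-table preprocessing in the fixed
  order filter → related-peak grouping → QC-anchored drift/batch correction
  → probabilistic quotient normalization → kNN imputation → glog variance
  stabilization, followed by dual-contrast attribution of features to
  producer strains (X-Y vs X-X and X-Y vs Y-X, Welch t-tests with BH per
  contrast per day), row Z-scoring, and a monoisotopic adduct-m/z
  annotator (e.g. DFO-B C25H48N6O8 [M+2H]2+ → 281.184).
- **`coculture.colonyquant`** — colony segmentation from plate photographs
  (binary threshold → connected components → pixel areas), pixel→mm²
  conversion anchored on the plate rim, pairwise t-tests with BH plus a
  Tukey HSD mode, and 30×30 well-scan aggregation with dose-response fits.
- **`coculture.enrichment`** — hypergeometric pathway over-representation
  of up/down-regulated gene sets (log-gamma tail, minimum gene-set size,
  BH).
- **`coculture.pipeline` / CLI** — end-to-end orchestration from one YAML
  config with a hashed run manifest; deterministic under a fixed seed.

Sample labels follow the `FOCAL-PARTNER` convention: in `"A-C"`, strain A
is the one sampled, grown next to partner C. Full sample ids look like
`A-C_d4_r2` (day 4, replicate 2).

## CLI

```sh
coculture simulate --outdir sim --seed 1           # synthetic inputs + truth
coculture rnaseq --reads lib.fastq --genomes genomes.fasta \
    --rrna rrna.fasta --annotation annotation.tsv --outdir rnaseq_out
coculture metabolomics --peaks sim/inputs/peaks.tsv \
    --meta sim/inputs/peak_samples.tsv --focal A --partner C
coculture colonies --images sim/inputs --plate-mm 90 --out areas.tsv
coculture enrich --de de.tsv --ko gene2ko.tsv --pathways ko2path.tsv \
    --direction up
coculture run --config config.yaml                 # full pipeline + manifest
```

A minimal `config.yaml`:

```yaml
outdir: my_run
seed: 1
strains: [A, C]
days: [2, 4]
replicates: 3
```

## Notes on statistical scope

The differential-expression test is deliberately **not** a DESeq2
reimplementation: dispersions are moderated method-of-moments estimates
(per-gene values shrunk toward the pooled central value), and there is no
LFC shrinkage, no Cook's-distance filtering and no independent-filtering
optimization beyond a fixed base-mean floor. Its null behaviour is
calibrated by simulation in the test suite. Adduct annotation is a plain
m/z matcher, not a probabilistic annotation model.
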