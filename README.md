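# cleavefeat

Site-level RNA cleavage-efficiency analysis from degradome sequencing:
score cleavage sites from 5′-end count tracks, build an exhaustive
window/region feature space (sequence, secondary-structure stability,
ribosome occupancy), prune it by rank-correlation rules, and select
features with L1/L2-penalized linear regression. A synthetic degradome
generator with planted effects makes every stage testable offline.

## Concepts

- **Cleavage score (site)** — degradome 5′-end reads at a transcript
  position divided by the gene's capped-read total (its abundance proxy);
  the gene-level score is the sum over the gene's sites. Genes need more
  than 50 cap reads to be scored.
- **Ribosome occupancy (site/gene/region)** — the analogous ratio for
  ribosome-protected-fragment reads.
- **Reliability filters** — keep genes with > 20% cleaved positions
  relative to transcript length and a gene-level score strictly inside the
  5th–95th percentile band; optionally drop externally predicted
  miRNA-cleavage sites; then split genes 9:1 into train/test.
- **Features** — around-site sliding windows (no offset 0; −1/+1 flank the
  cut, +1 is the detected 5′ nucleotide): nucleotide/codon/amino-acid
  frequencies over ±30 nt (lengths 1–60, step 1), structure energies over
  ±30 (lengths 5–60, step 5), occupancy means over ±200; plus whole-RNA
  features per region (5′-UTR/CDS/3′-UTR/whole): k-mer frequencies,
  region fold energy, occupancy sums, 50-nt end blocks, and 10-codon CDS
  start/stop blocks.
- **Pruning** — drop features with |Spearman r| to the score below 0.1,
  then greedily keep, in decreasing |r| order, only features whose pairwise
  |Spearman| with everything already kept stays below 0.6.
- **Models** — LASSO/Ridge of (by default) log10 score on z-scored
  features; λ on the objective scale `RSS + λ·penalty` (sklearn mapping:
  `alpha = λ/(2n)` for L1, `alpha = λ` for L2), chosen by gene-grouped
  10-fold CV (largest λ within 5% of the minimal CV MSE) or fixed
  explicitly.

The default structure backend is a weighted base-pair-maximization dynamic
program (GC −3, AU −2, GU −1, minimum hairpin loop 3); ViennaRNA can be
plugged in via `FeatureConfig(fold_backend="vienna")` when its Python
bindings are installed.

## Command line

```sh
cleavefeat simulate --config sim.yaml --seed 5 --out sim/
cleavefeat score --fasta sim/transcripts.fasta --regions sim/regions.tsv \
    --cap sim/cap.tsv --degradome sim/degradome.tsv --rpf sim/rpf.tsv \
    --min-cap-reads 50 --min-cleaved-frac 0.20 --percentile-band 5,95 \
    --split 0.9 --seed 5 --out score/
cleavefeat featurize --fasta sim/transcripts.fasta --regions sim/regions.tsv \
    --sites score/sites.tsv --cap sim/cap.tsv --rpf sim/rpf.tsv \
    --feature-config feat.yaml --out matrix.tsv
cleavefeat prune --matrix matrix.tsv --target-r 0.1 --pair-r 0.6 \
    --out pruned.tsv --report prune_report.tsv
cleavefeat fit --matrix pruned.tsv --penalty l1 --lambda auto --folds 10 \
    --seed 5 --features all --out fit/
cleavefeat evaluate --matrix pruned.tsv --model fit/model.json --split test
cleavefeat report --matrix pruned.tsv --model fit/model.json --out coef.json
cleavefeat predict --matrix new_matrix.tsv --model fit/model.json --out pred.tsv
```

`--features sequence-only` (and `featurize --sequence-only`) drops
structure and occupancy columns, the mode used for predicting sites of
genes without profiling data. Every stage writes a `manifest.json` with
input digests, parameters and seeds.

### File formats (all plain text)

- transcripts: FASTA plus a 3-column region TSV (`id`, `cds_start`,
  `cds_end`; 0-based half-open, CDS length divisible by 3); `T` is read as
  `U`.
- count tracks: TSV (`transcript_id`, `position`, `count`) of 5′-end reads,
  one file per track kind (degradome / cap / rpf); duplicate rows sum.
- feature matrix: TSV with `#feature` metadata header lines (name,
  category, scope, region, window, token) followed by one row per site.
- models and reports: JSON.

## Layout

```
src/cleavefeat/
  transcript_io.py       # readers/writers, FeatureMatrix persistence
  cleavage_scoring.py    # abundance, cleavage/occupancy tables, filters, split
  feature_extraction/    # windows, folding, feature specs, matrix builder
  feature_pruning.py     # target-correlation filter + greedy decorrelation
  penalized_models.py    # L1/L2 fits, CV, evaluation, coefficient reports
  synthetic_data.py      # generative model, planted effects, recovery report
  pipeline_cli.py        # the `cleavefeat` command
```
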