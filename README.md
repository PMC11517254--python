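# neoprior

Neoantigen prioritization from combined peptide-HLA (pHLA) and
peptide-HLA-TCR (pHLA-TCR) binding ranks, with supporting TCRβ repertoire
statistics, labeled-dataset assembly, rank-coverage evaluation and ELISpot
fold-change calls.

## What it does

- **repertoire** — read TCRβ clonotype tables (AIRR-style TSV), compute
  Shannon entropy / clonality, rarefaction curves, cross-sample clonotype
  sharing and V/J segment usage.
- **dataset_assembly** — load labeled pHLA-TCR complexes, build negatives
  by pairing each positive pHLA with randomly drawn TCRs (default 10 per
  pHLA, excluding known positive partners), deduplicate, and split 70/30
  into peptide-disjoint discovery/validation sets.
- **feature_engine** — map complexes to a two-feature representation
  (pHLA percentile rank, pHLA-TCR rank; 0–100, lower = stronger) via
  pluggable predictor adapters: file-based lookup tables for externally
  computed scores, or a deterministic synthetic stand-in. Includes the
  per-peptide minimum aggregations and the mutant-vs-wild-type filter.
- **immunogenicity_model** — train LR / RF / XGB candidates (XGB backed by
  scikit-learn's `HistGradientBoostingClassifier`), select by 10-fold
  stratified CV mean ROC AUC, fix operating thresholds at target
  specificities (default 0.95 / 0.99), report AUC with bootstrap CI and
  sensitivity/specificity/PPV/NPV; plus the fixed-2%-cutoff quadrant
  analysis with Pearson chi-square tests.
- **prioritization** — per-patient candidate ranking with top-k flags and
  the rank coverage score (group-level coverage reading; element-level
  variant behind a flag), including per-patient and pooled method
  comparisons.
- **elispot_validation** — mutant vs wild-type IFN-γ fold changes, calls
  at the 2-fold cutoff (inclusive by default), per-method summaries.
- **synthetic_data** — generators for every input: Zipf-ranked clone
  counts, class-conditional rank features, Poisson ELISpot counts.

## CLI

```bash
neoprior simulate complexes --seed 1 --out sim/         # complexes + features
neoprior simulate repertoire --seed 1 --out sim/
neoprior repertoire --input sim/ --rarefaction-depths 100,1000 --out rep/
neoprior assemble --positives pos.tsv --tcr-pool pool.txt --neg-per-phla 10 \
    --split 0.7 --split-unit peptide --seed 1 --out asm/
neoprior features --complexes asm/discovery.tsv --phla-scores phla.tsv \
    --ptcr-scores ptcr.tsv --out features.tsv
neoprior train --features features.tsv --algorithms lr,rf,xgb --folds 10 \
    --spec 0.95,0.99 --seed 1 --out model/
neoprior quadrant --features features.tsv --cutoff 2.0 --out quad/
neoprior prioritize --scores scores.tsv --direction higher-better --top-k 3 \
    --out ranked.tsv
neoprior rankscore --ranked ranked.tsv --out rankscore.json
neoprior elispot --counts counts.csv --cutoff 2.0 --out eli/
neoprior pipeline --config pipeline.yaml --seed 1 --out pipe/   # end to end
```

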