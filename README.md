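# enhanseq

Enhancers are distal regulatory DNA elements that activate transcription
through chromatin looping. They carry no fixed consensus sequence, which
makes them hard to find computationally and expensive to map
experimentally. `enhanseq` is a toolkit for supervised enhancer
identification: it turns labelled genomic regions into five groups of
features, trains a random-forest classifier, prunes the feature set by
recursive elimination, and reports cross-validated performance. It is
aimed at regulatory-genomics analysts who have a set of candidate regions
(e.g. from ChIP-Seq of enhancer-associated factors) and want a sequence- or
chromatin-based predictive model plus a ranked list of informative
features.

## Model

Each region is described by up to five feature blocks:

| Group | Features | Source |
|---|---|---|
| I | mean DNA structural properties over di-/tri-nucleotide sliding windows | sequence |
| II | TF binding motif occurrence: one TRAP occupancy per PWM | sequence |
| III | normalised k-mer composition (k = 1..6, no reverse-complement collapsing) | sequence |
| IV | per-track chromatin peak overlap indicators + their sum | ChIP-Seq peaks |
| V | input-subtracted RPM read densities per TF | ChIP-Seq counts |

The Group II score is the biophysical expected occupancy of the region by
a factor with binding preference **M** (a 4×W count matrix). Every window
*i* on both strands contributes a saturating term

```
score = Σ_i  R0 e^{-E_i} / (1 + R0 e^{-E_i}),
E_i   = (1/λ) Σ_j ln[(c_max,j + p) / (c_obs,j + p)],
R0    = exp(0.584 W − 5.66),   λ = 0.7,   p = 1
```

so a consensus match (E = 0) contributes ≈ R0/(1+R0) and mismatched
windows decay exponentially.

The classifier is a random forest (default 5000 trees). Feature selection
follows the out-of-bag (OOB) recursive-elimination scheme: rank features
once by OOB mean-decrease-accuracy importance, repeatedly drop the
least-important 10% and refit, then keep the smallest feature set whose
OOB error is within one standard error of the minimum. Feature relevance
is calibrated by refitting on permuted labels (p = (b+1)/(B+1)).
Performance is reported as sensitivity, specificity, accuracy, Matthews
correlation (MCC) and the tie-aware ROC AUC under stratified 10-fold
cross-validation.

## Worked example

Everything below runs on synthetic data generated by the package itself —
a toy genome whose "enhancers" are enriched for five planted PWMs hidden
among 45 uninformative decoys:

```bash
enhanseq simulate --seed 3 --outdir fixtures/
enhanseq features seq --genome fixtures/genome.fa --regions fixtures/pos.bed \
    --control-regions fixtures/neg.bed --pwms fixtures/pwms.txt \
    --groups II --out fm.tsv
# 600 regions x 50 features -> fm.tsv
enhanseq select --matrix fm.tsv --ntree 150 --ntree-iterat 100 --seed 1 --out trace.json
# selected 5/50 features -> trace.json
enhanseq eval --matrix fm.tsv --ntree 150 --folds 5 --seed 1 --out report.json
# AUC 0.9656  ACC 0.9083  MCC 0.8168 -> report.json
```

The elimination trace descends from 50 features (OOB error 0.087) to the
five planted motifs — `trace.json` lists exactly
`trap_planted_01 … trap_planted_05` — and cross-validation of the full
matrix reports AUC 0.9656: the motif-occupancy features recover the
planted regulatory signal almost perfectly, while the decoys are
discarded. The remaining error is the ~5% of enhancers that, at an
average of 3 insertions, received no motif by Poisson chance.

The same study can be driven from one YAML file with
`enhanseq run --config cfg.yaml`, which writes `report.json`,
`trace.json`, `importance.tsv` and `roc.tsv` into a run directory;
`enhanseq features chip` builds the peak-overlap and RPM blocks.

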