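# Methods

## Scope and data model

`enhanseq` classifies labelled genomic regions (positive = enhancer,
negative = control) from five feature blocks, selects informative features
by OOB-driven recursive elimination, and evaluates by stratified
cross-validation. All coordinates are BED-style 0-based half-open
intervals; regions are unstranded; region length is `end − start` and
equals the extracted sequence length. Sequences are uppercased on input
and every character outside ACGTN becomes N.

## Feature construction

**Group I — DNA structural properties.** A property is a lookup table over
all di- or tri-nucleotides (k = 2 or 3). The feature is the mean table
value over every sliding window of the region, on the given strand only.
Windows containing N are skipped; a region whose windows are all skipped
scores 0 (with a warning) rather than aborting a matrix build. The
packaged default table contains 23 scales (15 dinucleotide, 8
trinucleotide) and is a deterministic **synthetic stand-in** with realistic
dynamic range — measured structural tables (helical twist, bendability,
stacking energies, …) are proprietary to their sources and should be
supplied by the user as a TSV (`name, k, kmer:value …` per row) for real
analyses. Nothing downstream depends on the table's provenance: the
operation is a windowed table average.

**Group II — TRAP motif occupancy.** For each PWM the region score is the
expected occupancy under the TRAP biophysical model: for every window on
both strands, mismatch energy
`E = (1/λ) Σ_j ln((c_max,j + p)/(c_obs,j + p))` and occupancy term
`R0·e^(−E)/(1 + R0·e^(−E))`, summed. Reverse-strand windows use the energy
of the reverse-complemented window, which makes the score exactly
invariant under reverse complementation of the input. Defaults follow the
published TRAP parameterisation: λ = 0.7, pseudocount p = 1, and a
width-dependent equilibrium constant `R0 = exp(0.584·W − 5.66)`; all are
overridable (`TrapParameters`), as is an optional `log1p` transform of the
raw occupancy sum (off by default — the raw sum is the feature). Windows
containing N contribute zero occupancy: unknown bases never fabricate
affinity. PWMs whose columns sum to ≈1 are treated as frequency matrices
and rescaled by 100 before the pseudocount so one count-based energy model
serves all inputs. PWMs wider than the sequence score 0 with a warning.

**Group III — k-mer composition.** Exact overlapping occurrence counts of
each listed k-mer (k = 1..6) divided by the window count `L − k + 1`
(never less than 1); N windows cannot match but stay in the denominator,
so the composition over the complete k-mer set of one k sums to 1 exactly
on N-free sequences. No reverse-complement collapsing. Curated k-mer lists
are read from a one-per-line file; absent a curated list, the fallback is
the complete set of k-mers up to a maximum k (default 3, i.e. 84
features).

**Group IV — chromatin state.** One 0/1 indicator per peak track
(≥ 1 bp half-open overlap) plus a summary feature equal to the indicator
sum, so 64 tracks yield 65 features. "Region contains a peak" admits a
stricter reading — the peak lying entirely inside the region — exposed as
`mode="containment"`; overlap is the default because a histone-mark peak
wider than a 500 bp region should still count as presence of the mark.

**Group V — TF RPM densities.** `rpm = count/(total_mapped/1e6)/length`,
and the feature is `rpm(TF) − rpm(matched input)`. The subtraction is
oriented so enrichment is positive; values may be negative. Counts arrive
pre-tabulated per region (`#total_mapped=` header + id/count rows);
BAM/bigWig handling is deliberately out of scope.

## Classifier, elimination, permutation importance

The forest (scikit-learn trees, default ntree = 5000, mtry = √p,
bootstrap) reports OOB error and an **unscaled OOB mean-decrease-accuracy
importance** computed per tree: accuracy on the tree's OOB samples minus
accuracy after permuting one feature's values among those samples,
averaged over trees. This matches the classical forest importance rather
than a held-out-set permutation.

Recursive elimination (`VarSelRF`): fit the full model once and rank
features by that initial importance — importances are *not* recomputed in
later iterations, so early random fluctuations cannot compound. Then
repeatedly drop the least-important `round(drop_fraction × current)`
features (minimum 1; drop_fraction default 0.1), refit with a cheaper
forest (ntree_iterat = 2000; the initial fit keeps ntree = 5000), and
record OOB error ± its binomial SE `sqrt(e(1−e)/n)`, down to 2 features.
Selected is the smallest recorded set with OOB error ≤ min + c_sd·SE(min),
c_sd default 1.0; c_sd = 0 degenerates to the smallest OOB-minimising set.
Importance ties break by feature-name lexicographic order, making the
whole trace deterministic per seed.

Permutation importance (`RFPermuteImportance`): refit on `n_perm` (default
100) seeded permutations of the labels, collect each feature's null
importances, and report `p = (b + 1)/(B + 1)` with `b` the count of null
values ≥ observed — the add-one estimator that keeps p in (0, 1].

All randomness derives from one master seed through numpy
`SeedSequence.spawn`: forest fit, importance permutation stream, each
elimination refit, each label permutation, and each CV fold draw their own
child, so any stage reproduces independently. Seeds handed to scikit-learn
are reduced mod 2³¹.

## Evaluation

Stratified K-fold CV (K default 10): ids are sorted, shuffled per class
with the seeded generator and dealt round-robin, so per-class fold sizes
differ by ≤ 1. Each region is scored exactly once by the forest trained on
the other folds; the positive-class vote fraction ≥ 0.5 (configurable)
predicts positive. The headline numbers pool all held-out scores (per-fold
reports are attached as well) — pooled was chosen because it weights every
region equally and makes "every sample scored once" checkable. MCC uses
the 0/0 → 0 convention. AUC is scikit-learn's tie-aware rank statistic;
the test-suite cross-checks it against an exhaustive positive×negative
pair-counting oracle, and the TRAP scanner against a per-window
brute-force enumeration over all sequences up to 8 bp.

## Pipeline

`run_pipeline` executes build → (optional) selection → CV → permutation
importance and writes `features.tsv`, `report.json`, `trace.json`,
`importance.tsv`, `roc.tsv`. By default selection runs once on the full
matrix *before* CV, reproducing the classical protocol; this leaks label
information into the CV estimate, so a `nested: true` mode reruns the
elimination inside every training fold for a leakage-free (and more
expensive) estimate. Outputs contain no timestamps and JSON keys are
sorted: identical config + seed ⇒ byte-identical artifacts.

## Synthetic data generator

The generator emulates the statistical structure of an enhancer study,
not its biology: i.i.d. uniform-ACGT chromosomes (4 × 200 kb); 300
non-overlapping 500 bp enhancers; a PWM collection of 5 planted
high-information matrices (one dominant base per column, count 85/100,
widths 6–10) among 45 near-uniform decoys (Dirichlet(50) columns,
< 0.5 bit/column); Poisson(3) consensus insertions per enhancer at random
offsets/strands (consensus planting keeps the signal analytically
checkable; a PWM-sampling mode exists behind `plant_mode="sample"`);
length-matched same-chromosome shifted controls, rejection-sampled against
overlap with any positive (capped at 1000 attempts for guaranteed
termination); 64 peak tracks covering positives/negatives with probability
0.9/0.1 (the region ± ≤ 50 bp jitter); and 5 (TF, input) Poisson count
pairs at 200 reads/kb with 4-fold enrichment in positives. Defaults were
chosen once as a realistic desk-scale study: ~45% of enhancers carry any
given planted motif, so single features are weak and the forest must
combine them, while 5% of enhancers are motif-free by Poisson chance —
which is the source of the residual CV error.

What passing on this generator shows: the featurizers extract the planted
signal, the elimination recovers the truly informative features, and the
metrics behave correctly under known truth. What it does not show:
robustness to non-uniform genomic background (CpG islands, repeats),
correlated histone marks, fragment-level read structure, or motif
variants — real enhancer data differ in all four ways.

## Numerical choices and limitations

Energies are computed in log space and N windows are excluded via a −∞
penalty row, so no exp overflow occurs. Frequency-PWM detection uses a
1e-3 tolerance on column sums. The elimination's OOB errors are exact
forest outputs, not smoothed; with small n the SE-based stopping rule is
therefore conservative. Known limitations: selection-before-CV optimism
(documented above, nested mode provided); the forest is the only
classifier; no PR curves beyond the ROC export; genome-scale scanning
(sliding predictions along chromosomes) is not implemented — the unit of
prediction is a provided region.

Problem sizes used by the automated checks (chosen as desk-scale study
conditions): the default generator fixture above for recovery tests;
width-2 PWM × all 87,376 sequences ≤ 8 bp for the scanner oracle; 20,000
samples for the null-AUC baseline.
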