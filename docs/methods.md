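# Methods

`kmalpred` predicts lysine malonylation (Kmal) sites from protein sequence.
This note records the models, the conventions behind every numeric choice,
and what the bundled synthetic benchmark does and does not demonstrate.

## Problem setting

Malonylation is detected by mass spectrometry on a small fraction of the
lysines of a proteome. Given proteins and a table of identified sites, the
task is binary classification of each lysine from the 31-residue sequence
window centered on it (15 residues per side, `-` padding past the protein
termini). Positives are identified sites; negatives are the remaining
lysines of the same proteins — so negatives vastly outnumber positives, and
the practically relevant operating regime is the low-false-positive-rate
end of the ROC curve, summarized by the partial AUC below 10% FPR (AUC01,
reported raw with maximum 0.1).

## Dataset construction

1. **Confidence filter.** Positive sites are kept only with identification
   score > 50 and localization probability > 0.75; both inequalities are
   strict, and a positive missing either value is rejected with a warning.
2. **Redundancy reduction.** Proteins are clustered at > 30% identity by a
   greedy longest-first pass (each protein joins the first cluster whose
   seed exceeds the threshold, else founds one). Identity is computed as
   matches / alignment length from an edit-distance-optimal global
   alignment (edlib), with a shared-5-mer prefilter to skip hopeless pairs.
   We deliberately do not normalize by the shorter sequence length: under a
   gap-tolerant alignment that convention converges on the longest common
   subsequence ratio (~0.4 even for unrelated random proteins) and merges
   unrelated clusters wholesale. External cluster assignments (e.g. CD-HIT
   output) can be injected verbatim through the `assignments` hook.
   Per cluster, the member with the most positive sites is kept (ties:
   longer sequence, then lexicographically smaller id). A negative lysine of
   the representative is dropped — not relabeled — when another member
   carries a positive lysine with the identical ±3-residue 7-mer, a
   conservative stand-in for alignment-based correspondence.
3. **Conflict removal.** Any central 7-mer occurring in both a positive and
   a negative window removes every window carrying it, in both classes.
   The operation is idempotent.
4. **Grouped splitting.** Train/test splits and the 10-fold CV assign whole
   proteins, never windows, to a side; fold membership is a seeded
   permutation balanced by protein count. Peptide-level folds would leak
   near-identical windows from one protein across the split. All
   randomness is `numpy.random.default_rng(seed)`; seeds are echoed in
   output metadata.

## Encodings

* **EAAC** (enhanced amino-acid composition), the core traditional
  encoding: residue frequencies in an 8-residue window slid across the
  31-mer, 24 windows × 20 residues = 480 features, named in center-relative
  coordinates (`G[-5,2]` = glycine frequency over offsets −5..+2). The
  denominator is the fixed slide length 8: gaps and unknown residues add 0
  to every count, so terminal windows are diluted rather than renormalized.
  This keeps feature scales comparable across positions; the alternative
  (shrinking the denominator near termini) is not exposed.
* **AAC**: whole-window frequencies (20 features), gaps in the denominator
  only.
* **AAindex**: per-position values of physicochemical property scales
  (flat-file parser included; scales with any `NA` are dropped). Scales are
  ranked by the cross-validated AUC of a forest trained on one scale at a
  time, and the top 11 with AUC > 0.7 define a 31 × 11 = 341-dimensional
  encoding. Gap positions contribute 0.
* **One-hot**: 31 × 20 indicator matrix; gap rows are uniform 0.05 (each
  row sums to 1 either way).
* **Token sequence**: integer ids over the fixed alphabet
  `ACDEFGHIKLMNPQRSTVWY-` (alphabetical residues, gap id 20); the id map is
  persisted with every model bundle. Non-standard residues (B, J, O, U, X,
  Z) are folded to `X`, excluded from every composition count, and share
  the gap token.
* **Comparators** (benchmarking only): BLOSUM62 rows, flattened one-hot
  ("binary", 620), k-spaced residue-pair compositions (CKSAAP, k = 0..4,
  2000 features, each k-block normalized by its pair count), and the
  five-dimensional z-scales of Sandberg et al. (155 features).

## Classifiers

* **RF_EAAC**: 1000-tree random forest (scikit-learn) on EAAC. Candidate
  features per split are √d; using all d features would reduce the forest
  to bagged unrandomized trees, which we read as a description slip in the
  original account and expose only as an option. The score is the mean
  per-tree class probability; a Weka-style vote fraction is available
  (`score_mode="vote"`), and both agree on thresholded calls.
* **LSTM_WE**: embedding layer (21 symbols × 5 dimensions, learned) →
  single LSTM layer (32 units) → dropout 0.2 → dense ReLU layer (128) →
  dropout 0.2 → logistic output. **LSTM_one-hot** replaces the embedding
  with raw one-hot rows; **CNN_WE** replaces the recurrence with four 1-D
  convolution layers (64 filters, kernel 5, ReLU, same padding — free
  parameters, as is the global max pool before the output).
* The deep models are implemented directly in double-precision numpy with
  hand-written backpropagation, verified against finite differences in the
  test-suite. Training is minibatch Adam (default learning rate 1e-3,
  initialization Glorot-uniform with forget-gate bias 1 — recorded in
  model metadata) on the binary cross-entropy, computed on logits; the
  reference regimen is up to 300 epochs with batch size 512 and 20%
  dropout after the recurrent and dense layers. Dropout masks, batch order
  and initialization all derive from explicit seeds, so training is
  bit-reproducible; dropout is disabled at inference, and a non-finite
  loss aborts with a diagnostic rather than silently continuing. Optional
  early stopping monitors validation loss with a patience counter; the
  default is the fixed epoch budget.
* Model bundles (weights + JSON metadata: alphabet order, encoding id,
  window size, seeds, spec, version) round-trip exactly — reloaded models
  reproduce scores bit-for-bit (forests via joblib, deep nets via npz).

## Ensemble

The final score solves `log S/(1−S) = w1·C1 + w2·C2 + b`, with C1 the LSTM
score and C2 the forest score. The weights are plain maximum-likelihood
logistic regression (statsmodels `Logit`, no regularization, matching an R
`glm` fit) of the labels on **out-of-fold** component scores: each window
is scored by component models that never saw its protein in training, then
the weights are fit once on the pooled out-of-fold table (a per-fold refit
is the other defensible reading; pooled was chosen and is recorded here).
Training-set scores would bias the weights toward the more overfit
component. Degenerate inputs — a constant component, or scores that
separate the classes perfectly — raise an error naming the cause instead
of silently shrinking. The default operating threshold stored with a
trained predictor is the smallest ensemble score achieving specificity
≥ 0.90 on the out-of-fold scores (calls use the strict-greater rule; a
user-supplied threshold overrides).

## Evaluation

Accuracy, sensitivity, specificity and the Matthews correlation are
computed from the confusion table under the strict-greater call rule; MCC
is defined as 0 whenever a denominator factor vanishes (logged). The ROC
is a threshold sweep with tied scores collapsed into single steps, so the
trapezoid AUC equals the pairwise rank statistic P(s⁺ > s⁻) + ½P(tie) —
asserted against an exhaustive oracle in the tests. AUC01 integrates the
same curve over FPR ∈ [0, 0.1] by trapezoids with linear interpolation at
the cut (step integration would differ only at ROC vertices; trapezoid was
chosen and is fixed here), and is reported unnormalized (maximum 0.1) so
magnitudes are comparable with published values; a normalized variant
(÷0.1) is available but off by default. Harnesses are provided for
learning curves over protein-grouped subsamples (fractions ⅛, ¼, ½, 1 by
default) and for comparing window sizes (15..35) by rebuilding the dataset
per size.

## Interpretation

* **Two-sample logo statistics**: for every (position, residue) pair the
  per-window occurrence indicators of the positive and negative sets are
  compared with an unpooled two-proportion z-test — the large-sample
  equivalent of the two-sample t-test on 0/1 data — falling back to
  Fisher's exact test when any cell count is below 5. The Bonferroni
  family is all 30 × 20 = 600 pairs of a 31-mer (the constant center is
  excluded); cells with adjusted p < 0.05 are reported with direction.
* **Information gain**: label-entropy reduction in bits after supervised
  minimum-description-length (Fayyad–Irani) discretization of each
  feature; when MDL accepts no split the feature falls back to
  equal-frequency 10-bin discretization, and the binning actually used is
  recorded per feature. Both schemes are rank-based, so the ranking is
  invariant under strictly monotone feature transforms. Ties break
  lexicographically by feature name.
* **Embedding clustering**: the 20 amino-acid rows of the learned 21 × 5
  embedding (gap excluded) are clustered by average-linkage agglomeration
  under Euclidean distance; the merge history is exportable as Newick.

## Synthetic benchmark

The generator emulates the one property of malonylation data that the
package's statistics depend on: a position-specific composition signal
around labeled lysines. Proteins are drawn i.i.d. from a background
(uniform 1/20 by default, keeping analytic expectations simple); lysines
at least 8 residues apart are enrolled as sites, of which 20% are labeled
positive by default. Enrollment is label-blind: crowded lysines are left
out of the site table entirely rather than enrolled as automatic
negatives, because lysine crowding is sequence information, and coupling
it to the labels would hand every classifier a signal that has nothing to
do with the planted motif (and would pull the null configuration away
from AUC 0.5). Flank offsets carrying a motif effect are resampled
from the background tilted by a per-residue log-odds shift; the default
strong-effect condition plants glycine (+2.5) at offsets −4..+2 and
depletes lysine (−3.0) at −1..+2 in positives, and plants glutamate
(+1.5) at −4..+4 except −1 and +3 around negatives, mirroring the
enrichment pattern reported for real mammalian Kmal peptides. Identification
scores for positives are drawn from Normal(90, 20) and Beta(9, 1), so a
realistic tail fails the confidence filter. Five percent of proteins are
duplicated with light mutation (site 7-mers preserved) to exercise
clustering and aligned-counterpart exclusion.

Two generator subtleties are deliberate:

* Resampling touches only offsets that deviate from the background —
  effect-carrying offsets, plus any flank lysine of a positive site, which
  is redrawn from the lysine-free background. Planting a motif therefore
  never mints new lysine sites whose windows would carry the positive
  pattern under a negative label (left in, such sites cap the attainable
  AUC well below the intended strong-signal condition), and sites close
  together do not overwrite each other's planted flanks. The analytic
  per-offset distribution (`position_distribution`) matches the sampled
  process exactly under these rules.
* The null configuration (`SyntheticConfig.null()`) performs no resampling
  at all, so labels are independent of sequence by construction and any
  downstream AUC away from 0.5 indicates leakage.

What passing on this benchmark does **not** show: real proteomes have
non-uniform composition, homology structure beyond near-duplicates,
long-range dependence, and much heavier class imbalance; mass-spectrometry
evidence is modeled as two fixed distributions, not physically. Absolute
AUCs on the synthetic benchmark are not comparable to published AUCs on
proteomic data; the benchmark demonstrates correctness of the machinery
(signal in → signal recovered; no signal in → chance out), not field
performance.

## Problem sizes and scaled-down settings

The default benchmark uses 2000 proteins of mean length 60 (~5700 windows
after redundancy reduction, ~18% positive). The CV harnesses in the
acceptance runs train the LSTM for 20 epochs at learning rate 2e-3 — at
this data size the loss plateau is reached well before that — while
forests always use the full
1000 trees; the null check uses 300 trees, since the tree count does not
move the null expectation. The reference 300-epoch regimen remains the
default for trained predictors. The learning-curve and window-size
harnesses accept any (train, eval) → scores method, so cheap surrogates
can stand in for full models in exploratory runs.

## Known limitations

* The internal clustering is a greedy approximation of CD-HIT: single-pass,
  representative-vs-candidate comparisons only, no banded heuristics. At
  proteome scale (10⁵ sequences) it is quadratic in the number of clusters;
  the assignment hook exists for exactly that case.
* Aligned-counterpart exclusion requires exact 7-mer equality; diverged
  homologous sites (any flank substitution) escape it.
* The numpy deep-learning engine is single-threaded and CPU-bound; it is
  sized for desk-scale experiments (~10⁴ windows), not proteome-scale
  training.
* `rank_aaindex_properties` retrains one forest per property per fold;
  ranking hundreds of scales at full tree count is expensive and should be
  done once and cached.
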