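# Methods

`pancnv` implements a three-stage pipeline for classifying tumour types
from discrete copy-number matrices: Monte Carlo Feature Selection (MCFS)
to rank features, Incremental Feature Selection (IFS) to pick how many
of them to keep, and a self-normalizing neural network (SNN) — with a
random-forest baseline — to do the classifying. This note records the
model, the parameters that matter, the numerical choices, and what the
synthetic cohorts do and do not establish.

## Input model

A cohort is a samples × features table of discrete copy-number states
plus a tumour-type label per sample. The default state alphabet is the
GISTIC thresholded convention {−2, −1, 0, +1, +2} (deep loss, shallow
loss, neutral, gain, amplification); both the alphabet and its
interpretation are configurable, since thresholded copy-number tables in
the wild vary in coding and in whether rows are genes or peaks. Matrices
are stored samples-in-rows; GISTIC emits genes × samples, so real tables
must be transposed on ingest.

## Synthetic cohorts

The generator (`pancnv.synthetic`) emulates that table shape with known
ground truth. Noise features are iid categorical draws with probabilities
(0.05, 0.15, 0.60, 0.15, 0.05) over the five states — most mass neutral,
symmetric tails — for every sample regardless of class. A planted
informative feature is re-drawn, in exactly one designated class, from
the same distribution with a fraction `effect_strength` of the neutral
mass moved to one extreme state (+2 or −2). Planted columns are chosen
uniformly at random (seeded), assigned to classes round-robin, with
gain/loss direction alternating so each class's signature uses both
tails. `effect_strength = 0` makes planted features statistically
identical to noise (the null used by the no-signal tests);
`effect_strength = 0.8`, the desk default, puts ≈53% of a planted
feature's mass on its tail state within its class versus 5% elsewhere —
a strong, recurrent alteration of the kind GISTIC is designed to flag.

What the generator deliberately does not model: correlation between
features (real CNV features are strongly correlated along chromosome
arms), class-unbalanced noise, batch structure, or missing values.
Passing tests therefore demonstrate that the machinery ranks, selects
and classifies correctly when the signal is of the planted form; they do
not certify accuracy figures on real TCGA cohorts, where correlated
features make both ranking and the choice of prefix harder.

Two presets fix the study conditions. `paper` mirrors the original
four-cancer cohort dimensions: 518 + 597 + 372 + 597 = 2,084 samples and
23,109 features. `desk` is sized for a single CPU: 4 × 100 samples,
2,000 features, 40 planted (10 per class) at effect 0.8.

## MCFS

`s` feature subsets of size `m` are drawn uniformly without replacement
from the `M` features; for each subset, `t` decision trees are grown on
independent stratified train/held-out splits (fraction 2/3 for
training), giving `s·t` trees. Each feature `f` accumulates

    RI_f = Σ_τ (wAcc_τ)^u · Σ_{n_f(τ)} IG(n_f(τ)) · (n(n_f(τ)) / n(τ))^v

over all trees τ and all nodes n_f(τ) that split on `f`, where `IG` is
the split's information gain in bits, the fraction is the node's share
of the tree's training samples, and `wAcc` is the tree's weighted
accuracy — mean per-class recall — on its held-out split. Features are
ranked by RI descending, ties broken lexicographically by feature ID.

Choices the method leaves open, and how this package resolves them:

- **u, v** default to 1 (the common MCFS setting); both are exposed.
- **wAcc** is measured per tree on held-out samples. Training-set wAcc
  would saturate at 1 for deep trees and stop discriminating tree
  quality.
- **Split type**: binary threshold splits over the ordered states
  (`state ≤ θ`), because copy-number states are ordinal. Each node picks
  the (feature, threshold) pair maximizing information gain; ties go to
  the lowest feature index, then the lowest threshold.
- **Stopping**: a node becomes a leaf when pure, smaller than
  `min_samples_split` (default 2), at `max_depth` (default unbounded),
  or when the best gain is ≤ 1e−12 — the tolerance absorbs float noise
  in the entropy arithmetic so "no real gain" never forces a split.
- **Defaults** `s = 300`, `m = ⌈0.05·M⌉` (min 5), `t = 5` are
  conventional MCFS settings; nothing in the score depends on them
  structurally, only the Monte Carlo resolution does.

The interdependency-discovery extension of published MCFS (ID graphs)
and permutation-based RI significance cutoffs are out of scope.

## IFS

Given the ranking F = [f1 … fM], the i-th candidate subset is the first
i·k features. A coarse scan evaluates each candidate by stratified
cross-validated accuracy and macro F1; the best prefix is the accuracy
argmax, ties broken toward higher macro F1, then toward fewer features.
A second, fine stage re-scans every size (configurable stride) inside an
interval around the coarse optimum. With `fine_interval="auto"` the
interval runs from the smallest coarse prefix whose accuracy is within
1% (relative) of the coarse maximum — the plateau onset — through the
coarse argmax. Per-prefix CV seeds are derived from the global seed and
the prefix size alone, so curve points do not depend on evaluation order
and overlapping coarse/fine sizes agree exactly.

Desk-scale scan settings: `k = 50` up to 500 of the 2,000 features
(the same ~25% coverage a full-scale scan of 5,000 from 23,109 uses),
3-fold CV inside the scan, fine stride 25, and a final 10-fold
evaluation at the selected prefix.

## SNN classifier

A feed-forward network with three hidden layers of 200 units. Hidden
activations use the scaled exponential linear unit

    selu(x) = λ·x              (x > 0)
    selu(x) = λ·α·(e^x − 1)    (x ≤ 0),    λ = 1.0507, α = 1.6733,

whose fixed-point dynamics pull activations toward zero mean and unit
variance layer after layer, provided inputs are standardized and weights
are drawn from N(0, 1/fan_in) (biases zero). Regularization is alpha
dropout: dropped units are set to the SELU saturation value −λα and an
affine correction restores the (0, 1) moments in expectation, so dropout
does not break self-normalization. The output layer is linear with a
softmax; training minimizes multiclass cross-entropy with mini-batch
Adam.

**Input encoding.** Discrete CNV states are expanded to one indicator
column per state before standardization (`encode_states=True`). The
states are categories of alteration — amplification is not "twice a
gain" — and the indicator coding lets the network weight each alteration
type separately. Empirically this matters: on desk cohorts the ordinal
coding caps an MLP (and linear models) well below what trees achieve,
while the indicator coding restores the ceiling. Standardization
statistics (per indicator column) are computed on the training fold
only; constant columns are kept with their scale forced to 1 and a
logged warning.

Training hyperparameters (100 epochs, batch 64, learning rate 1e−3,
dropout 0.05) are exposed in `SNNConfig`; the desk IFS scan uses 40
epochs with batch 128, which is past convergence at those problem sizes.
Determinism: one seeded generator drives initialization, batch order and
dropout masks, so identical data + seed reproduce identical weights.

## Random-forest baseline

scikit-learn's `RandomForestClassifier` (500 trees, √m features per
split by default) wrapped in the same fit/predict contract as the SNN,
so either classifier plugs into IFS and cross-validation unchanged. The
forest consumes the ordinal state values directly — trees split
ordinally, consistent with the MCFS tree design.

## Evaluation

Accuracy is trace over total of the pooled held-out confusion matrix;
macro F1 is the unweighted mean of one-vs-rest F1 scores, with the
convention that a class with no true and no predicted positives
contributes F1 = 0 (logged). Folds are stratified by class and seeded.
For balanced classes, weighted accuracy (mean per-class recall)
coincides with plain accuracy; the tests exercise that identity.

## Reproducibility and problem sizes

Every stage consumes a seed derived from one global seed by stable
hashing (CRC-32 of a stage tag fed into NumPy's `SeedSequence`), so a
pipeline run is reproducible byte-for-byte from its manifest, and any
stage can be re-run in isolation. The shipped test suite and the
acceptance script run entirely at desk scale (≤ 2,000 features,
≤ 1,000 MCFS trees, ≤ 500 samples), chosen so a full pipeline completes
in about a minute on one CPU; the full-scale preset generates the full
2,084 × 23,109 cohort but ranking and scanning it is a multi-hour batch
job left to the user.

## Known limitations

- Planted features are independent; feature correlation would let
  redundant features share RI and shift the IFS optimum in ways these
  tests do not probe.
- The auto fine interval assumes a curve that rises to a plateau; a
  multimodal IFS curve can make the interval miss an off-plateau
  optimum (the exhaustive fine stride 1 covers whatever interval is
  given, but the interval itself comes from the coarse grid).
- The SNN is a CPU NumPy implementation; it is sized for thousands of
  input columns, not for GPU-scale architecture search.
- Headline accuracies on the real TCGA cohort depend on that external
  dataset and are not reproduced or asserted here.
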