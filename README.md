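# pancnv

Pan-cancer tumour-type classification from discrete copy-number
matrices: **Monte Carlo Feature Selection** (MCFS) to rank tens of
thousands of CNV features, **Incremental Feature Selection** (IFS) to
decide how many to keep, and a **self-normalizing neural network** (SNN)
— with a random-forest baseline — to classify, all evaluated by
stratified cross-validation.

The package is aimed at computational-biology practitioners who have a
GISTIC-style thresholded copy-number table (samples × features of
discrete states such as {−2, −1, 0, +1, +2}) with a tumour-type label
per sample, and want a reproducible, fully seeded feature-selection +
classification pipeline. A synthetic-cohort generator with planted
class-informative features makes every stage testable end to end with no
external data.

## The method

**MCFS** draws *s* random subsets of *m* of the *M* features and grows
*t* decision trees per subset on stratified train/held-out splits. Each
feature *f* is scored by its relative importance

```
RI_f = Σ_τ (wAcc_τ)^u · Σ_{n_f(τ)} IG(n_f(τ)) · ( n(n_f(τ)) / n(τ) )^v
```

summing over all s·t trees τ and every node n_f(τ) splitting on *f*:
`IG` is the split's information gain (bits), the fraction is the node's
share of the tree's samples, and `wAcc` — mean per-class recall on the
tree's held-out split — weighs the whole tree's quality (defaults
u = v = 1). Sorting by RI gives the ranked list F = [f1, …, fM].

**IFS** evaluates a classifier by cross-validation on nested prefixes
[f1…f_{ik}] of that list (coarse step *k*, then a fine scan of every
size around the coarse optimum) and selects the prefix with the best
accuracy (ties → higher macro F1, then fewer features).

**SNN**: a feed-forward net (three hidden layers × 200 units) using the
scaled exponential linear unit `selu(x) = λx` for x > 0 and
`λα(eˣ − 1)` for x ≤ 0, with λ = 1.0507, α = 1.6733, weights drawn from
N(0, 1/fan_in) and alpha dropout — together these hold activations at a
zero-mean/unit-variance fixed point through depth, without batch
normalization. Performance is reported as accuracy and macro F1 (mean
one-vs-rest F1 across classes).

## Worked example

Run the full pipeline on the built-in desk-scale synthetic cohort
(4 classes × 100 samples, 2,000 features, 40 planted informative
features) — about a minute on one CPU:

```bash
pancnv pipeline --preset desk --seed 5 --out runs/desk
```

prints

```json
{
  "best_n": 50,
  "metrics": {
    "snn": {
      "accuracy": 0.985,
      "macro_f1": 0.9850490655455706
    },
    "rf": {
      "accuracy": 0.9725,
      "macro_f1": 0.9725280912719925
    }
  }
}
```

Reading: the IFS scan selected the top **50** MCFS-ranked features (the
cohort has 40 planted ones, which the ranking pushes to the front); at
that prefix a 10-fold cross-validated SNN classifies 98.5% of samples
correctly with macro F1 0.985, slightly ahead of the 500-tree random
forest on the same subset (97.25%). `runs/desk/` holds the cohort
(`matrix.tsv`, `labels.tsv`), the ground-truth planted features, the
ranking (`ranking.tsv`), both IFS curves (`ifs_coarse.csv`,
`ifs_fine.csv`), the trained model directory, the evaluation reports
and confusion matrix, and a `manifest.json` recording every seed,
config value and stage timing — re-running with the same seed
reproduces every artifact byte for byte.

The stages are also available separately (`pancnv simulate`, `rank`,
`ifs`, `train`, `evaluate`; see `--help`), and as library functions:

```python
from pancnv import (CohortSpec, generate_cohort, MCFSConfig, mcfs_rank)

matrix, planted = generate_cohort(CohortSpec(
    n_per_class=(50, 50), n_features=500,
    n_informative_per_class=10, effect_strength=0.8, seed=7))
ranking = mcfs_rank(matrix, MCFSConfig(s=100, m=25, t=5, seed=7))
print(ranking.top(10))
```

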