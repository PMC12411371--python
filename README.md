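# reprofeat

Tools for studying whether the **test–retest reproducibility** of features
and their **predictive value** are actually related — a question that
matters wherever large panels of correlated, noisy measurements (e.g.
image-derived "radiomic" features) are screened for biomarker candidates by
first discarding features whose repeat measurements disagree.

The package provides:

- **Lin's concordance correlation coefficient (CCC)** for paired replicate
  measurements,

  ρ<sub>c</sub> = 2·s<sub>xy</sub> / (s<sub>x</sub>² + s<sub>y</sub>² + (x̄ − ȳ)²),

  with population (divide-by-*n*) moments, applied per feature to aligned
  replicate tables, plus mean ± 95 % CI aggregation across repeated runs.
- An **"elephants in the house" simulator**: houses (subjects) that either
  contain one elephant (label 1) or none, observed through binary room
  indicators (features) at two timepoints. The elephant moves between
  rooms, so every individual room indicator is non-concordant between
  timepoints — yet the OR over rooms identifies occupied houses with AUC
  exactly 1. Reproducibility and predictiveness come apart by
  construction: with R rooms and prevalence p, the per-room CCC tends to
  (1 − p)/(R − p) (= 0.2 for R = 3, p = 0.5), far below the conventional
  0.70 "reproducible feature" cutoff.
- A **synthetic replicate-study generator**: correlated continuous features
  with a target CCC ("reliability") per feature, binary labels, and class
  signal placed either in the most reliable features (`concentrated`), or
  spread one-hot across the least reliable ones (`distributed`, the
  continuous elephant mechanism), or absent (`null`).
- A **threshold-sweep pipeline**: per repeat, compute per-feature CCC from
  the two training replicates, split features at a threshold ϑ into
  reproducible (CCC > ϑ, strict) and nonreproducible sets, train a
  LASSO-selected random-forest classifier on each of
  {all, reproducible, nonreproducible}, and score held-out data with AUC,
  AUPRC, F1, sensitivity and specificity (the last three at the
  Youden-optimal ROC point).

## Worked example

```python
import numpy as np
from sklearn.metrics import roc_auc_score
import reprofeat as rf

# The toy: 200 houses, 3 rooms, half occupied, two timepoints.
ds = rf.simulate_houses(rf.ElephantConfig(n_houses=200, n_rooms=3,
                                          prevalence=0.5, seed=7))
print("per-room CCC:", np.round(rf.per_feature_ccc(ds), 3))
print("OR-rule AUC:", roc_auc_score(ds.labels, rf.or_rule_scores(ds.X2)))

# The pipeline on a synthetic study whose signal is spread across the
# three LEAST reliable features (distributed regime), threshold 0.75.
res = rf.run_experiment(rf.preset("distributed", seed=7), grid=(0.75,), repeats=5)
summ = rf.summarize(res)
auc = summ[summ.metric == "auc"]
print(auc[["feature_set", "mean", "ci_lo", "ci_hi", "n_missing"]].to_string(index=False))
```

Output:

```
per-room CCC: [0.061 0.099 0.227]
OR-rule AUC: 1.0
    feature_set     mean    ci_lo    ci_hi  n_missing
            all 0.858329 0.840200 0.876457          0
nonreproducible 0.863609 0.842322 0.884896          0
   reproducible 0.518240 0.484856 0.551624          0
```

Every room indicator has CCC around 0.06–0.23 — "nonreproducible" by any
common threshold — yet the OR rule classifies perfectly. In the
distributed regime the model restricted to *nonreproducible* features
(mean AUC ≈ 0.86) clearly beats the model restricted to reproducible ones
(≈ 0.52): filtering features by test–retest concordance before modeling
would have discarded all of the signal.

## Command line

```bash
reprofeat elephant   --seed 3 --out runs          # toy cohort + per-room CCC
reprofeat samplesize --config cfg.yaml --out runs # CCC uncertainty vs cohort size
reprofeat pipeline   --config cfg.yaml --out runs # threshold-sweep experiment
reprofeat fixtures   --out fixtures --seed 0      # small frozen demo datasets
```

Each run writes a timestamped directory with `manifest.yaml` (resolved
configuration, seed, package version), `log.txt` and the result CSVs; all
randomness is derived from the single `--seed`.

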