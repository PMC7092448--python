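# ssshd

Stable sparse feature selection for high-dimensional **class-imbalanced**
binary data, built around a Hellinger-distance tuning criterion.

The selector fits an elastic-net penalized linear SVM over a grid of penalty
strengths and mixes, scores every candidate by the Hellinger distance between
the two classes' decision-score distributions (a quantity that is insensitive
to the class-imbalance ratio and to score translation), and stabilizes the
selected support by repeating the search over stratified subsamples. Features
are ranked by their inclusion frequency — the fraction of subsampling runs in
which their coefficient is nonzero.

The package also ships the comparison toolkit used to validate the method:

- `ssshd.hellinger` — closed-form Hellinger distance between two normals and
  its plug-in estimator on class-split decision scores.
- `ssshd.sparse_svm` — elastic-net hinge-loss SVM (numba coordinate descent,
  warm-started paths, exact zeros, optional near-exact FISTA polish).
- `ssshd.core` — HD-maximizing grid tuning (cross-fitted scores by default),
  stability selection, rankings, top-q selection.
- `ssshd.metrics` — confusion rates, G-mean, F-measure, ROC / PR curves and
  the conservative lower-trapezoid area rule.
- `ssshd.baselines` — Fisher score, Relief, per-feature ROC/PR-area filters,
  and accuracy-/ROC-driven grid tuning for head-to-head comparisons.
- `ssshd.resampling` — SMOTE oversampling, stratified k-fold, leave-one-out,
  stratified subsampling.
- `ssshd.simulation` — blocked-AR(1) two-class Gaussian generator and the
  replication harness comparing the ACC / ROC / HD tuning criteria by
  correctly/incorrectly selected feature counts and FDR.
- `ssshd.io` / `ssshd.cli` — delimited-table I/O (minority auto-mapped to
  +1), the end-to-end selection workflow, YAML run manifests.

## Library quick start

```python
import numpy as np
from ssshd import stability_select, rank_features, select_top_q

rng = np.random.default_rng(0)
X = rng.standard_normal((200, 50))
X[:160, 0] -= 1.0          # majority shifted on feature 0
y = np.array([-1] * 160 + [1] * 40)

res = stability_select(X, y, K=100, fraction=0.5, seed=0)
print(rank_features(res)[:10])      # most stable features first
print(select_top_q(res, 5))
```

## Command line

```bash
# rank features of a CSV/TSV table (label column auto-mapped, minority -> +1)
ssshd select --data expr.csv --label-column class --method ssshd \
      --runs 100 --fraction 0.5 --qs 1,2,3,5,10 --seed 1 --out results/

# filter baselines: --method fisher | relief | aucroc | aucprc

# SMOTE re-balancing to a 1:1 ratio
ssshd smote --data expr.csv --k 5 --seed 1 --out balanced.csv

# cross-validated metrics for top-q subsets of an existing ranking
ssshd evaluate --data expr.csv --ranking results/ranking.tsv \
      --qs 1,3,5 --protocol loocv --out metrics.tsv

# synthetic benchmark comparing the acc / roc / hd tuning criteria
ssshd simulate --scenario A --ratio 9:1 --reps 50 --seed 1 --out table.tsv
```

`select` also accepts a YAML config (`--config run.yaml`; flags override it)
and writes a `manifest.yaml` recording the configuration, seed and package
versions alongside each output.

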