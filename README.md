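# chemgen

Multi-drug machine-learning prediction and imputation of cancer drug
sensitivity (IC50) from cell-line genomics and drug chemistry.

## Scientific problem

Large pharmacogenomic screens measure the concentration of a drug that
inhibits half of a cancer cell line's viability (the IC50) across panels of
hundreds of cell lines and drugs. These screens are expensive and always
incomplete: a substantial fraction of the cell-line × drug matrix is never
measured. `chemgen` trains a *single* regression model across all drugs
jointly — each training instance concatenates the genomic features of one
cell line (copy-number state, sequence variants and microsatellite
instability, encoded as {−1, 0, 1}) with the chemical descriptors of one drug
(physicochemical properties and fingerprint bits) — so that information is
shared across drugs and missing entries of the screen can be imputed.

The core model is a one-hidden-layer perceptron trained with resilient
backpropagation (RPROP), with its hidden-layer size and stopping iteration
selected as the minimum of a cross-train RMSE landscape; a random-forest
regressor serves as an independent baseline. IC50 values are mapped to (0, 1)
with the logistic transform `f(x) = 1 / (1 + (x/m)^-k)` (midpoint `m` = 1 µM,
slope `k` = 1) for training, and all reported metrics (Pearson Rp, coefficient
of determination R², RMSE) are computed on the log10 IC50 scale. Three
cross-validation schemes are provided: random 8-fold over matrix entries,
*stringent* cell-line-disjoint folds, and tissue hold-out. Predicted IC50s
can be screened for drug-to-oncogene sensitivity associations (Welch t-test
of altered vs wild-type cell lines, Benjamini–Hochberg FDR control) and
compared with associations found in the experimental values.

Because real screen data cannot ship with the package, a seeded synthetic
generator draws screens with known ground truth — sparse-linear drug
baselines from chemical descriptors, marker-gene effects, cell-line offsets,
planted gene × drug-class sensitivity interactions, Gaussian noise and
missing-at-random gaps — so that every pipeline stage can be validated
against planted structure.

## Worked example

```python
from chemgen import (
    SyntheticConfig, generate_dataset, make_random_folds,
    evaluate_fold_plan, discover_associations,
)
import numpy as np

# draw a small synthetic screen: 40 cell lines x 10 drugs, 30% missing
config = SyntheticConfig(n_cells=40, n_drugs=10, missing_fraction=0.3, seed=3)
dataset, truth = generate_dataset(config)
print(f"screen: {dataset.ic50.values.shape[0]} cell lines x "
      f"{dataset.ic50.values.shape[1]} drugs, {dataset.n_observed} observed IC50s")

# 8-fold cross-validation of the multi-drug perceptron
plan = make_random_folds(dataset.ic50.observed_entries(), k=8, seed=3)
result = evaluate_fold_plan(dataset, plan, model="mlp",
                            hidden_units=(8, 16, 24), max_iter=300, seed=3)
print(result.pooled)

# drug-to-oncogene sensitivity associations from the experimental IC50s
assoc = discover_associations(np.log10(dataset.ic50.values), dataset.genomic.values)
sig = sorted([r for r in assoc if r.significant], key=lambda r: r.q_value)
print(f"{len(assoc)} tested pairs, {len(sig)} significant at FDR 0.2")
top = sig[0]
print(f"top hit: {top.drug_id} ~ {top.feature_id} "
      f"(effect {top.effect:+.2f} log10 units, q={top.q_value:.2g})")
```

Output:

```
screen: 40 cell lines x 10 drugs, 278 observed IC50s
[pooled] n=278  Rp=0.809  R2=0.644  RMSE=0.706
495 tested pairs, 23 significant at FDR 0.2
top hit: D9 ~ seq:G01 (effect -2.51 log10 units, q=1.3e-05)
```

The top hit is one of the generator's planted sensitizing interactions: cell
lines carrying a `G01` sequence variant respond about 300× more strongly
(−2.5 log10 units) to drugs of that class.

A command-line interface mirrors the API:

```bash
chemgen --seed 3 simulate --out screen/          # write a synthetic screen as CSVs
chemgen load-check screen/ic50.csv screen/genomic.csv screen/descriptors.csv
chemgen --seed 3 crossval screen/ic50.csv screen/genomic.csv screen/descriptors.csv \
        --scheme random --k 8
chemgen assoc screen/ic50.csv screen/genomic.csv screen/descriptors.csv
```

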