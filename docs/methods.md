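# Methods

## Overview

`chemgen` predicts and imputes IC50 drug-sensitivity values for cancer cell
lines by training a single regression model over all (cell line, drug) pairs
of a screen jointly. Each observed entry of the cell-line × drug response
matrix becomes one training instance whose feature vector concatenates the
cell line's encoded genomic profile with the drug's chemical descriptors.
Pooling all drugs into one model lets chemically similar drugs and
genomically similar cell lines share statistical strength, which is what
makes imputation of unmeasured entries possible.

## Data model and encoding

**Response matrix.** IC50 values (µM) in a cell-line × drug matrix; `NaN`
marks unmeasured entries. Values must be strictly positive. Reported
metrics use the log10 scale.

**Genomic features.** Per cell line, for each gene of a cancer-gene panel:

- a copy-number slot: amplification (more than 7 copies) → +1, wild type
  (1–7 copies) → 0, deletion (0 copies) → −1;
- a sequence-variant slot: variant → 1, wild type → 0;
- one cohort-wide microsatellite-instability slot: unstable → 1, stable → 0.

A panel of G genes yields 2·G + 1 slots. Curation drops cell lines with more
than 15 missing slots (`max_missing_features`, default 15); after curation,
any slot still missing for at least one retained cell line is dropped, so the
surviving feature matrix is complete. The missingness filter runs before any
constancy consideration.

**Chemical descriptors.** Continuous physicochemical properties and binary
fingerprint bits per drug. Descriptors missing for any drug are dropped
first (universality), then descriptors constant across all drugs (no
information) — in that order.

**IC50 normalization.** Targets are mapped to (0, 1) with the logistic
transform `f(x) = 1 / (1 + (x/m)^(−k))` with midpoint `m = 1 µM` and slope
`k = 1`. The transform is strictly monotone and invertible, so predictions
are mapped back to concentrations exactly (predictions are clipped away from
0 and 1 by 1e-12 before inversion to keep the logs finite). Training happens
in normalized space; evaluation happens in log10 IC50 space.

## Models

### Multi-drug perceptron (RPROP)

A one-hidden-layer perceptron: sigmoid hidden layer, sigmoid output (matching
the (0, 1) target range), trained by batch resilient backpropagation (RPROP)
on the summed squared error. RPROP adapts one step size per weight from
gradient sign agreement:

- same sign as last iteration → step × η⁺ (1.2);
- sign flip → step × η⁻ (0.5), the update is suppressed for that iteration
  and the stored gradient zeroed;
- steps clipped to [Δmin, Δmax] = [1e-6, 50]; initial step Δ0 = 0.1;
- weights move by −sign(gradient) · step.

These are the standard resilient-backpropagation defaults; RPROP needs no
learning-rate tuning, which suits a landscape search over architectures.

**Architecture selection.** For each candidate hidden-layer size *h* the
network is trained for up to `max_iter` iterations (default 400) from a fresh
seeded initialization, recording the cross-train RMSE after every iteration.
The selected architecture (h, t) is the global minimum of this
size × iteration RMSE surface; ties resolve to the smaller size, then the
earlier iteration. The default size grid is 1–30. The cross-train set is
used *only* for this selection and never for gradient updates; the test set
is never touched during training. Selection RMSE is computed in normalized
space (the space the loss is optimized in); reported performance is in log10
space.

**Defaults and rationale.** `validation_fraction = 0.125` splits off an
internal cross-train set when none is supplied (mirrors one bin of eight);
`init_scale = 0.5` gives uniform initial weights in ±0.5, small enough to
start the sigmoids in their responsive range.

### Random forest baseline

`RandomForestIC50Regressor` pins a scikit-learn `RandomForestRegressor` to
500 trees (the conventional size at which performance plateaus for this task;
all other parameters are library defaults). The forest needs no architecture
selection, so cross-train entries join its training set.

### Single-drug baselines

One small perceptron per drug, trained only on that drug's entries and only
on the genomic feature block (chemical descriptors are constant within one
drug and carry no information there). Default grid {1, …, 10} hidden units.
Drugs with fewer than 2 entries in any fold role are skipped and reported.

## Validation schemes

- **Random 8-fold**: observed entries are distributed into k = 8 near-equal
  bins; rotation i uses bin i as test, bin i+1 as cross-train, the remaining
  six as training. Each entry is tested exactly once, giving 8 models whose
  pooled test predictions form the primary metric; per-rotation metrics are
  secondary.
- **Stringent (cell-line-disjoint)**: cell lines, not entries, are
  partitioned, so no cell line contributes to two roles of the same rotation.
  This measures generalization to unseen cell lines.
- **Tissue hold-out**: every entry of one tissue's cell lines is the test
  set; the remaining cell lines are split cell-line-disjointly 7:1 into train
  and cross-train.
- **Training-set downsampling**: a sparsity experiment keeps a random
  fraction of each rotation's train+cross-train entries (test sets
  untouched), emulating a sparser screen on identical test sets.

## Metrics

Pearson correlation Rp, coefficient of determination
R² = 1 − SSres/SStot, and RMSE, computed between observed and predicted
log10 IC50 on test entries only; pooled over all rotations (primary) and per
rotation (secondary). With zero variance in either vector Rp is undefined
and reported as NaN rather than silently substituted.
`r2_mode="squared_pearson"` switches R² to the squared correlation for
comparability with conventions that report it that way.

## Association analysis

For every (drug, genomic feature) pair, cell lines with a non-zero feature
value form the *altered* group; Welch's two-sample t-test compares the two
groups' log10 IC50 values on that drug's observed entries. Pairs with either
group below `min_group = 3` are flagged untested. The effect is
mean(altered) − mean(wildtype); its sign is the *tendency* (negative =
sensitizing). P-values are Benjamini–Hochberg adjusted across the entire
pair family and flagged significant at q ≤ FDR (default 0.2, a deliberately
permissive screening threshold for hypothesis generation).

**Recapitulation.** Associations are discovered twice: from experimental
IC50s and from cross-validated test-set predictions (never in-sample fits).
Over the experimentally significant pairs we report the fraction whose
predicted-side tendency agrees and the fraction that is also significant on
the predicted side with matching tendency.

## Synthetic screen generator

The generator draws screens with known ground truth so that the pipeline can
be validated against planted structure. The log10 IC50 surface is

```
log10 IC50(c, d) = baseline(d) + Σ_g marker_g · variant(c, g)
                   + offset(c) + Σ planted interactions + N(0, σ)
```

- **baseline(d)**: sparse linear function of the drug's chemical descriptors
  (20% non-zero coefficients, N(0, 0.15)) — drugs with similar chemistry get
  similar potency, the signal the multi-drug model exploits;
- **marker genes**: 8 genes with main effects N(0, 0.5) on all drugs;
- **cell offsets**: N(0, 0.2) per cell line (general sensitivity);
- **planted interactions**: 3 gene × drug-class effects of −2.0 log10 units
  for variant carriers — strong sensitizing associations the discovery stage
  should find;
- **noise**: σ = 0.3; **missingness**: 42% missing completely at random (a
  biased mode instead truncates each cell line's drug list to the same
  count).

Defaults: 100 cell lines × 20 drugs, 30 genes, 60 descriptors (30 continuous
+ 30 fingerprint bits), 4 tissues, 4 drug classes, mutation probability 0.2,
amplification/deletion probability 0.05 each, MSI probability 0.2. The
default geometry is a desk-scale stand-in for a real screen (hundreds of cell
lines × ~100 drugs, ~58% fill): the fill fraction, encoding scheme, fold
schemes and association family structure are faithful; the absolute entry
count is roughly 30× smaller.

**What it emulates**: chemistry-driven shared structure across drugs,
genomic markers with directional effects, screen sparsity, tissue grouping,
discoverable planted associations with an oracle
(`planted_association_oracle`).
**What it does not emulate**: dose-response curve-fitting error structure,
correlated missingness tied to assay failures, linked genomic events
(co-occurring mutations, copy-number/expression coupling), inter-drug
correlations beyond descriptor similarity, and realistic class imbalance of
rare alterations.

## Numerical choices

- Architecture selection minimizes normalized-space RMSE (the training
  objective's space); reported metrics are log10-space.
- Predictions are clipped to [1e-12, 1 − 1e-12] before inverting the
  logistic transform.
- All stochastic steps (screen draw, fold assignment, weight initialization,
  downsampling) take explicit integer seeds; per-rotation seeds are drawn
  from a seeded generator so rotations are independent but reproducible.
- The benchmark (`chemgen.benchmark.run_benchmark`) uses a reduced
  architecture grid {8, 16, 24} × 300 iterations for the multi-drug model
  and {1, 2, 4, 8} × 150 for single-drug models, keeping a full run in the
  minutes range; the full 1–30 grid is the library default.

## Limitations

- Desk-scale screens (~1,160 observed entries) leave every model
  data-starved relative to a real screen; absolute scores are
  condition-bound and should be compared within a configuration, not across
  scales.
- With ~100 cell lines of nearly unique genotype, random entry-level folds
  let a model memorize per-cell-line offsets, inflating random-fold scores
  relative to cell-line-disjoint folds; the gap shrinks as the panel grows.
- The perceptron trains full-batch; very large screens would need batching
  or a different optimizer.
- Association discovery treats features marginally; it does not model
  covariates or linked alterations.
- The RPROP implementation is single-threaded NumPy; the random forest uses
  one core by default.
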