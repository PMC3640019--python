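"""Standard synthetic-screen benchmark: every headline experiment in one place.

Runs the full pipeline on the default synthetic screen -- 8-fold
cross-validation with the multi-drug perceptron and the random forest, the
cell-line-disjoint and tissue-hold-out schemes, the training-sparsity curve,
the multi-drug versus single-drug comparison, and association recapitulation
-- and returns every quantity as a flat mapping.

The perceptron runs with a reduced landscape grid (hidden units {8, 16, 24},
300 iterations; the full search typically selects sizes in the low twenties
after roughly 300 iterations) and per-drug models with {1, 2, 4, 8} / 150,
keeping a complete benchmark in the minutes range on one core.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .associations import compare_association_sets, discover_associations, predictions_to_matrix
from .evaluation import compute_metrics, evaluate_fold_plan, sparsity_experiment
from .features import assemble_instances
from .folds import make_cellline_disjoint_folds, make_random_folds, make_tissue_holdout
from .models import train_single_drug_models
from .synthetic import SyntheticConfig, generate_dataset, planted_association_oracle

__all__ = ["run_benchmark", "BENCHMARK_HIDDEN_GRID", "BENCHMARK_MAX_ITER"]

logger = logging.getLogger("chemgen")

BENCHMARK_HIDDEN_GRID = (8, 16, 24)
BENCHMARK_MAX_ITER = 300
SINGLE_DRUG_GRID = (1, 2, 4, 8)
SINGLE_DRUG_MAX_ITER = 150
SPARSITY_FRACTIONS = (0.2, 0.6, 1.0)


def _per_drug_medians(predictions: pd.DataFrame, instances) -> dict[str, float]:
    rows = []
    for drug, grp in predictions.groupby("drug"):
        if len(grp) < 2:
            continue
        obs = instances.log10[
            instances.index_of(list(zip(grp["cell_line"], grp["drug"])))
        ]
        rep = compute_metrics(obs, grp["log10_ic50"], scope=str(drug))
        rows.append((rep.pearson_rp, rep.r_squared, rep.rmse))
    arr = np.asarray(rows)
    return {
        "rp": float(np.nanmedian(arr[:, 0])),
        "r2": float(np.median(arr[:, 1])),
        "rmse": float(np.median(arr[:, 2])),
    }


def run_benchmark(seed: int = 1, config: SyntheticConfig | None = None) -> dict[str, float]:
    """Run every standard experiment on one synthetic screen draw.

    ``seed`` drives the screen draw, all fold plans and all weight
    initializations.  Returns a flat name -> value mapping (fractions on the
    percentage-free scale the metrics use, counts as floats).
    """
    cfg = config or SyntheticConfig(seed=seed)
    dataset, truth = generate_dataset(cfg)
    instances = assemble_instances(dataset)
    entries = dataset.ic50.observed_entries()
    mlp_kw = dict(model="mlp", hidden_units=BENCHMARK_HIDDEN_GRID,
                  max_iter=BENCHMARK_MAX_ITER, seed=seed)

    out: dict[str, float] = {
        "n_observed_entries": float(len(entries)),
        "n_features": float(instances.X.shape[1]),
    }

    # 8-fold random cross-validation, multi-drug MLP and random forest
    plan = make_random_folds(entries, k=8, seed=seed)
    cv_mlp = evaluate_fold_plan(dataset, plan, instances=instances, **mlp_kw)
    out["cv_pearson_mlp"] = cv_mlp.pooled.pearson_rp
    out["cv_r2_mlp"] = cv_mlp.pooled.r_squared
    out["cv_rmse_mlp"] = cv_mlp.pooled.rmse
    logger.info("random-fold MLP: %s", cv_mlp.pooled)

    cv_rf = evaluate_fold_plan(dataset, plan, model="rf", seed=seed, instances=instances)
    out["cv_pearson_rf"] = cv_rf.pooled.pearson_rp
    out["cv_r2_rf"] = cv_rf.pooled.r_squared
    out["cv_rmse_rf"] = cv_rf.pooled.rmse
    logger.info("random-fold RF: %s", cv_rf.pooled)

    # stringent (cell-line-disjoint) and tissue-hold-out schemes
    stringent = evaluate_fold_plan(
        dataset, make_cellline_disjoint_folds(entries, k=8, seed=seed),
        instances=instances, **mlp_kw,
    )
    out["stringent_cv_r2"] = stringent.pooled.r_squared
    out["stringent_cv_pearson"] = stringent.pooled.pearson_rp
    out["stringent_cv_rmse"] = stringent.pooled.rmse
    logger.info("stringent MLP: %s", stringent.pooled)

    tissue = sorted(set(dataset.tissues.values()))[0]
    holdout = evaluate_fold_plan(
        dataset, make_tissue_holdout(entries, dataset.tissues, tissue, seed=seed),
        instances=instances, **mlp_kw,
    )
    out["tissue_holdout_r2"] = holdout.pooled.r_squared
    out["tissue_holdout_pearson"] = holdout.pooled.pearson_rp
    out["tissue_holdout_rmse"] = holdout.pooled.rmse
    out["n_tissue_holdout_entries"] = float(holdout.pooled.n_entries)
    logger.info("tissue hold-out (%s) MLP: %s", tissue, holdout.pooled)

    # training-sparsity curve on the same test sets
    curve = sparsity_experiment(
        dataset, SPARSITY_FRACTIONS, plan, seed=seed, model="mlp",
        hidden_units=BENCHMARK_HIDDEN_GRID, max_iter=BENCHMARK_MAX_ITER,
    )
    r2s = curve.r_squared()
    for f, v in r2s.items():
        out[f"sparsity_r2_at_{int(100 * f)}pct"] = v
    out["sparsity_r2_drop_60_to_20"] = r2s[0.6] - r2s[0.2]

    # multi-drug vs per-drug baselines (genomic features only)
    sd_preds, skipped = train_single_drug_models(
        instances, plan, n_genomic_features=len(dataset.genomic.feature_ids),
        hidden_units=SINGLE_DRUG_GRID, max_iter=SINGLE_DRUG_MAX_ITER, seed=seed,
    )
    med = _per_drug_medians(sd_preds, instances)
    out["single_drug_median_pearson"] = med["rp"]
    out["single_drug_median_r2"] = med["r2"]
    out["single_drug_median_rmse"] = med["rmse"]
    out["n_single_drug_models_skipped"] = float(len(skipped))

    # association recapitulation: experimental vs predicted-side discovery
    experimental = discover_associations(
        np.log10(dataset.ic50.values), dataset.genomic.values
    )
    predicted = discover_associations(
        predictions_to_matrix(cv_mlp.predictions), dataset.genomic.values
    )
    recap = compare_association_sets(experimental, predicted)
    out["n_experimental_significant"] = float(recap.n_experimental_associations)
    out["assoc_tendency_agreement_pct"] = 100.0 * recap.fraction_same_tendency
    out["assoc_significant_overlap_pct"] = 100.0 * recap.fraction_recovered_significant

    oracle = planted_association_oracle(truth)
    out["n_planted_associations"] = float(len(oracle))
    exp_sig = {(r.drug_id, r.feature_id): r.tendency for r in experimental if r.significant}
    pred_sig = {(r.drug_id, r.feature_id): r.tendency for r in predicted if r.significant}
    out["planted_assoc_recall_experimental_pct"] = 100.0 * np.mean(
        [exp_sig.get(k) == v for k, v in oracle.items()]
    )
    out["planted_assoc_recall_predicted_pct"] = 100.0 * np.mean(
        [pred_sig.get(k) == v for k, v in oracle.items()]
    )
    return out
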