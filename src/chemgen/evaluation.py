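"""Test-set evaluation: Pearson correlation, coefficient of determination and
RMSE on the log10 IC50 scale, fold-plan execution, and sparsity curves.

R-squared is the true coefficient of determination, 1 - SS_res / SS_tot
(``r2_mode="squared_pearson"`` switches to the squared correlation).  Metrics
are computed exclusively on test-role entries, pooled over all rotations
(primary) and per rotation (secondary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Dataset
from .features import InstanceSet, LogisticNormalizer, assemble_instances
from .folds import FoldPlan, downsample_training
from .models import predict as _predict
from .models import train_mlp, train_random_forest

__all__ = [
    "EvaluationReport",
    "CrossValidationResult",
    "compute_metrics",
    "evaluate_fold_plan",
    "sparsity_experiment",
    "plot_prediction_scatter",
]

logger = logging.getLogger("chemgen")


@dataclass(frozen=True)
class EvaluationReport:
    """Agreement between observed and predicted log10 IC50 on one entry set."""

    scope: str
    pearson_rp: float  # NaN flags the undefined (zero-variance) case
    r_squared: float
    rmse: float
    n_entries: int

    def __str__(self) -> str:  # human-readable one-liner
        return (
            f"[{self.scope}] n={self.n_entries}  Rp={self.pearson_rp:.3f}  "
            f"R2={self.r_squared:.3f}  RMSE={self.rmse:.3f}"
        )


def compute_metrics(
    observed, predicted, scope: str = "overall", r2_mode: str = "determination"
) -> EvaluationReport:
    """Rp, R-squared and RMSE between paired log10 IC50 vectors.

    With zero variance in either vector the Pearson correlation is undefined
    and reported as NaN; R-squared and RMSE are still returned.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be paired 1-d vectors")
    if len(obs) < 2:
        raise ValueError("need at least 2 paired values")
    if not (np.isfinite(obs).all() and np.isfinite(pred).all()):
        raise ValueError("non-finite values in metric inputs")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        rp = float("nan")
    else:
        rp = float(stats.pearsonr(obs, pred).statistic)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if r2_mode == "determination":
        if ss_tot == 0:
            r2 = float("nan")
        else:
            r2 = 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot
    elif r2_mode == "squared_pearson":
        r2 = rp**2
    else:
        raise ValueError(f"unknown r2_mode {r2_mode!r}")
    return EvaluationReport(scope, rp, r2, rmse, len(obs))


@dataclass
class CrossValidationResult:
    """Pooled and per-rotation reports plus the test-set predictions."""

    pooled: EvaluationReport
    per_rotation: list[EvaluationReport]
    predictions: pd.DataFrame  # provenance-carrying test-set predictions
    models: list = field(default_factory=list)

    @property
    def mean_per_rotation_r2(self) -> float:
        return float(np.mean([r.r_squared for r in self.per_rotation]))


def evaluate_fold_plan(
    dataset: Dataset,
    plan: FoldPlan,
    model: str = "mlp",
    hidden_units=(1, 2, 4, 8, 16),
    max_iter: int = 400,
    n_trees: int = 500,
    seed: int = 0,
    normalizer: LogisticNormalizer | None = None,
    instances: InstanceSet | None = None,
    keep_models: bool = False,
    r2_mode: str = "determination",
) -> CrossValidationResult:
    """Train one model per rotation and evaluate exclusively on its test set.

    ``model`` selects the learner: ``"mlp"`` (landscape-searched perceptron)
    or ``"rf"`` (random forest, whose cross-train entries join the training
    set since the forest needs no architecture selection).
    """
    normalizer = normalizer or LogisticNormalizer()
    if instances is None:
        instances = assemble_instances(dataset, normalizer)
    rng = np.random.default_rng(seed)
    frames, per_rotation, models = [], [], []
    for r, rot in enumerate(plan.rotations):
        rot_seed = int(rng.integers(2**31))
        if not rot.test:
            logger.warning("rotation %d has an empty test set; skipped", r)
            continue
        tr = instances.select(instances.index_of(rot.train))
        ct = instances.select(instances.index_of(rot.crosstrain))
        te = instances.select(instances.index_of(rot.test))
        if model == "mlp":
            fitted = train_mlp(
                tr, ct, hidden_units=hidden_units, max_iter=max_iter, seed=rot_seed
            )
        elif model == "rf":
            pool = instances.select(
                instances.index_of(list(rot.train) + list(rot.crosstrain))
            )
            fitted = train_random_forest(pool, n_trees=n_trees, seed=rot_seed)
        else:
            raise ValueError(f"unknown model {model!r}")
        preds = _predict(fitted, te, normalizer, model_id=f"{model}:{r}", rotation=r)
        if len(te) >= 2:
            per_rotation.append(
                compute_metrics(te.log10, preds["log10_ic50"], f"rotation:{r}", r2_mode)
            )
        frames.append(preds)
        if keep_models:
            models.append(fitted)
    if not frames:
        raise ValueError("every rotation had an empty test set")
    predictions = pd.concat(frames, ignore_index=True)
    obs = instances.log10[
        instances.index_of(list(zip(predictions["cell_line"], predictions["drug"])))
    ]
    pooled = compute_metrics(obs, predictions["log10_ic50"], "pooled", r2_mode)
    return CrossValidationResult(pooled, per_rotation, predictions, models)


@dataclass(frozen=True)
class SparsityCurve:
    """Evaluation reports at increasing training fractions, shared test sets."""

    points: tuple[tuple[float, EvaluationReport], ...]

    def __post_init__(self) -> None:
        fracs = [f for f, _ in self.points]
        if any(b <= a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("fractions must be strictly increasing")

    def r_squared(self) -> dict[float, float]:
        return {f: rep.r_squared for f, rep in self.points}


def sparsity_experiment(
    dataset: Dataset,
    fractions,
    plan: FoldPlan,
    seed: int = 0,
    **fit_kwargs,
) -> SparsityCurve:
    """Re-evaluate the fold plan with the training roles downsampled.

    The test sets are identical at every fraction, so the curve isolates the
    effect of screen sparsity on predictive power.
    """
    fractions = sorted(float(f) for f in fractions)
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    normalizer = fit_kwargs.pop("normalizer", None) or LogisticNormalizer()
    instances = assemble_instances(dataset, normalizer)
    points = []
    for f in fractions:
        sub = downsample_training(plan, f, seed=seed)
        res = evaluate_fold_plan(
            dataset, sub, seed=seed, normalizer=normalizer, instances=instances,
            **fit_kwargs,
        )
        rep = res.pooled
        points.append((f, EvaluationReport(f"fraction:{f:g}", rep.pearson_rp,
                                           rep.r_squared, rep.rmse, rep.n_entries)))
        logger.info("sparsity fraction %.2f: %s", f, points[-1][1])
    return SparsityCurve(tuple(points))


def plot_prediction_scatter(predictions: pd.DataFrame, observed_log10, path) -> None:
    """Observed vs predicted log10 IC50 scatter with the identity line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    obs = np.asarray(observed_log10, dtype=float)
    pred = predictions["log10_ic50"].to_numpy()
    rep = compute_metrics(obs, pred)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(pred, obs, s=6, alpha=0.4, edgecolors="none")
    lims = [min(pred.min(), obs.min()), max(pred.max(), obs.max())]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("predicted log10 IC50")
    ax.set_ylabel("observed log10 IC50")
    ax.set_title(f"Rp={rep.pearson_rp:.2f}  R2={rep.r_squared:.2f}  RMSE={rep.rmse:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
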