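"""Model training on assembled instances: multi-drug MLP, random forest,
single-drug baselines, prediction and ensembling.

All models regress the normalized response in (0, 1); predictions are carried
back to the log10 IC50 scale through the inverse of the logistic normalizer.
The random forest is a bagged regression-tree ensemble (500 trees by default)
provided as a non-parametric alternative to the perceptron.  Single-drug
baselines reuse the perceptron machinery on genomic features only -- within
one drug the chemical descriptors are constant and carry no information -- with
a reduced hidden-unit grid to respect the far smaller per-drug sample.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .features import InstanceSet, LogisticNormalizer
from .mlp import RpropMLPRegressor

__all__ = [
    "train_mlp",
    "RandomForestIC50Regressor",
    "train_random_forest",
    "predict",
    "ensemble_predict",
    "train_single_drug_models",
    "save_model",
    "load_model",
]

#: normalized outputs are clipped this far inside (0, 1) before inversion, so a
#: float-saturated sigmoid still maps to a finite concentration
_EPS = 1e-12

DEFAULT_HIDDEN_GRID = tuple(range(1, 31))
SINGLE_DRUG_HIDDEN_GRID = tuple(range(1, 11))


def train_mlp(
    train: InstanceSet,
    crosstrain: InstanceSet,
    hidden_units=DEFAULT_HIDDEN_GRID,
    max_iter: int = 400,
    seed: int | None = None,
    **kwargs,
) -> RpropMLPRegressor:
    """Fit the perceptron on a train set with an explicit cross-train set."""
    if len(train) == 0 or len(crosstrain) == 0:
        raise ValueError("train and cross-train sets must be non-empty")
    model = RpropMLPRegressor(
        hidden_units=hidden_units, max_iter=max_iter, random_state=seed, **kwargs
    )
    return model.fit(train.X, train.y, X_val=crosstrain.X, y_val=crosstrain.y)


class RandomForestIC50Regressor(RandomForestRegressor):
    """Random-forest regression on normalized responses (500 trees by default).

    Thin subclass pinning the recommended ensemble size; prediction is the
    mean over trees, which stays inside the convex hull of the (0, 1) targets.
    """

    def __init__(self, n_estimators: int = 500, random_state=None, n_jobs=None):
        super().__init__(
            n_estimators=n_estimators, random_state=random_state, n_jobs=n_jobs
        )


def train_random_forest(
    train: InstanceSet, n_trees: int = 500, seed: int | None = None
) -> RandomForestIC50Regressor:
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if len(train) == 0:
        raise ValueError("training set must be non-empty")
    model = RandomForestIC50Regressor(n_estimators=n_trees, random_state=seed)
    model.fit(train.X, train.y)
    return model


def _to_frame(
    instances: InstanceSet, y_norm: np.ndarray, normalizer: LogisticNormalizer,
    model_id: str, rotation: int,
) -> pd.DataFrame:
    y_norm = np.clip(y_norm, _EPS, 1 - _EPS)
    log10 = np.log10(normalizer.denormalize(y_norm))
    return pd.DataFrame(
        {
            "cell_line": instances.cells,
            "drug": instances.drugs,
            "y_norm": y_norm,
            "log10_ic50": log10,
            "model_id": model_id,
            "rotation": rotation,
        }
    )


def predict(
    model,
    instances: InstanceSet,
    normalizer: LogisticNormalizer | None = None,
    model_id: str = "model",
    rotation: int = 0,
) -> pd.DataFrame:
    """Predict a batch of instances; returns the provenance-carrying table."""
    normalizer = normalizer or LogisticNormalizer()
    y = model.predict(instances.X) if len(instances) else np.empty(0)
    return _to_frame(instances, y, normalizer, model_id, rotation)


def ensemble_predict(
    models,
    instances: InstanceSet,
    normalizer: LogisticNormalizer | None = None,
    model_id: str = "ensemble",
    rotation: int = -1,
) -> pd.DataFrame:
    """Arithmetic mean of member outputs in normalized space, then to log10 IC50."""
    normalizer = normalizer or LogisticNormalizer()
    if not models:
        raise ValueError("ensemble requires at least one model")
    y = np.mean([m.predict(instances.X) for m in models], axis=0)
    return _to_frame(instances, y, normalizer, model_id, rotation)


def train_single_drug_models(
    instances: InstanceSet,
    plan,
    n_genomic_features: int,
    hidden_units=SINGLE_DRUG_HIDDEN_GRID,
    max_iter: int = 400,
    seed: int = 0,
    min_entries_per_role: int = 2,
    normalizer: LogisticNormalizer | None = None,
):
    """Per-drug perceptrons on genomic features only, under a shared fold plan.

    For every drug, each rotation of ``plan`` is restricted to that drug's
    entries; rotations whose restricted train, cross-train or test set falls
    below ``min_entries_per_role`` are skipped, and a drug with no usable
    rotation is skipped entirely (returned in ``skipped``).

    Returns
    -------
    predictions : DataFrame
        Pooled test-set predictions with per-drug provenance.
    skipped : list of str
        Drugs without enough entries to train.
    """
    normalizer = normalizer or LogisticNormalizer()
    drugs = sorted(set(instances.drugs))
    frames, skipped = [], []
    rng = np.random.default_rng(seed)
    for drug in drugs:
        drug_seed = int(rng.integers(2**31))
        mask = instances.drugs == drug
        sub = instances.select(np.where(mask)[0])
        entry_set = set(zip(sub.cells, sub.drugs))
        produced = False
        for r, rot in enumerate(plan.rotations):
            tr = [e for e in rot.train if e in entry_set]
            ct = [e for e in rot.crosstrain if e in entry_set]
            te = [e for e in rot.test if e in entry_set]
            if min(len(tr), len(ct), len(te)) < min_entries_per_role:
                continue
            tr_i = instances.select(instances.index_of(tr))
            ct_i = instances.select(instances.index_of(ct))
            te_i = instances.select(instances.index_of(te))
            # genomic block only: descriptor columns are constant within a drug
            cols = slice(0, n_genomic_features)
            model = RpropMLPRegressor(
                hidden_units=hidden_units, max_iter=max_iter, random_state=drug_seed
            ).fit(tr_i.X[:, cols], tr_i.y, X_val=ct_i.X[:, cols], y_val=ct_i.y)
            y = model.predict(te_i.X[:, cols])
            frames.append(_to_frame(te_i, y, normalizer, f"single:{drug}", r))
            produced = True
        if not produced:
            skipped.append(drug)
    predictions = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["cell_line", "drug", "y_norm", "log10_ic50", "model_id", "rotation"])
    )
    return predictions, skipped


def save_model(model: RpropMLPRegressor, path) -> None:
    """Serialize a fitted perceptron (layer sizes, weights, selection metadata)."""
    payload = {
        "kind": "rprop_mlp",
        "n_features_in": int(model.n_features_in_),
        "hidden_units": int(model.hidden_units_),
        "n_iter": int(model.n_iter_),
        "crosstrain_rmse": float(model.crosstrain_rmse_),
        "hidden_grid": [int(h) for h in model.hidden_grid_],
        "coefs": [c.tolist() for c in model.coefs_],
        "intercepts": [b.tolist() for b in model.intercepts_],
        "params": {
            k: v for k, v in model.get_params().items() if np.isscalar(v) or v is None
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> RpropMLPRegressor:
    payload = json.loads(Path(path).read_text())
    if payload.get("kind") != "rprop_mlp":
        raise ValueError(f"{path}: not a serialized perceptron")
    model = RpropMLPRegressor()
    model.n_features_in_ = payload["n_features_in"]
    model.hidden_units_ = payload["hidden_units"]
    model.n_iter_ = payload["n_iter"]
    model.crosstrain_rmse_ = payload["crosstrain_rmse"]
    model.hidden_grid_ = payload["hidden_grid"]
    model.coefs_ = [np.asarray(c) for c in payload["coefs"]]
    model.intercepts_ = [np.asarray(b) for b in payload["intercepts"]]
    return model
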