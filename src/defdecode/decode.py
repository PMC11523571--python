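"""Gradient-boosted decision-tree regression of continuous behavior.

A thin, deterministic wrapper around LightGBM's L2-objective booster.
Models are trained per subject/session/behavior; the per-iteration
training loss is recorded, and evaluation reports both the coefficient
of determination R² = 1 − SS_res/SS_tot (range (−∞, 1], *not* the
squared Pearson correlation) and Pearson's r.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import json
import numpy as np
import lightgbm as lgb
from scipy import stats

from .markers import FeatureMatrix

__all__ = [
    "DEFAULT_PARAMS",
    "DecoderModel",
    "EvalResult",
    "fit_decoder",
    "predict",
    "r2_score",
    "pearson_r",
    "evaluate",
]

#: Default booster configuration. The number of trees and learning rate
#: are deliberately conservative; early stopping on the validation L2
#: loss (patience 50) prunes the ensemble when a validation set is given.
DEFAULT_PARAMS: dict[str, Any] = {
    "objective": "l2",
    "n_estimators": 500,
    "learning_rate": 0.05,
    "num_leaves": 31,
    "min_child_samples": 20,
    "early_stopping_rounds": 50,
    "boosting": "gbdt",
    "num_threads": 1,
    "deterministic": True,
    "verbosity": -1,
}


@dataclass
class DecoderModel:
    """A fitted GBDT ensemble with its feature names and loss trace."""

    booster: lgb.Booster
    feature_names: list[str]
    params: dict[str, Any]
    seed: int
    train_loss: np.ndarray = field(default_factory=lambda: np.empty(0))
    val_loss: np.ndarray | None = None

    def save(self, model_path, sidecar_path) -> None:
        self.booster.save_model(str(model_path))
        with open(sidecar_path, "w") as f:
            json.dump({"feature_names": self.feature_names,
                       "params": {k: v for k, v in self.params.items()},
                       "seed": self.seed}, f, indent=2, sort_keys=True)


@dataclass
class EvalResult:
    """Decoding performance on one split."""

    r2: float
    pearson_r: float
    kind: str = ""
    split: str = ""
    constant_prediction: bool = False


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, FeatureMatrix):
        return X.values, X.names
    return np.asarray(X, dtype=np.float64), None


def fit_decoder(X, y: np.ndarray, params: dict[str, Any] | None = None,
                seed: int = 0, X_val=None, y_val: np.ndarray | None = None,
                feature_names: list[str] | None = None) -> DecoderModel:
    """Train the L2-objective GBDT with a fixed seed.

    Deterministic given (data, params, seed) because the default
    configuration is single-threaded with LightGBM's deterministic mode.
    Records the per-iteration training L2 loss; when a validation set is
    supplied, also the validation loss, with early stopping.
    """
    Xm, names = _as_matrix(X)
    names = feature_names or names or [f"f{i}" for i in range(Xm.shape[1])]
    y = np.asarray(y, dtype=np.float64)
    if Xm.shape[0] == 0:
        raise ValueError("empty training set")
    if Xm.shape[0] != len(y):
        raise ValueError("X and y have different numbers of windows")
    if not (np.all(np.isfinite(Xm)) and np.all(np.isfinite(y))):
        raise ValueError("NaN or infinite values in the training inputs")

    p = dict(DEFAULT_PARAMS)
    p.update(params or {})
    p["seed"] = seed
    n_rounds = int(p.pop("n_estimators"))
    stopping = p.pop("early_stopping_rounds")

    # LightGBM forbids JSON-special characters in feature names; the
    # canonical names (which contain ',' and ':') live on the model.
    safe_names = [n.replace(",", ";").replace(":", "."
                  ).replace('"', "'") for n in names]
    train_set = lgb.Dataset(Xm, label=y, feature_name=safe_names,
                            params={"verbosity": -1})
    valid_sets = [train_set]
    valid_names = ["train"]
    callbacks = []
    evals: dict[str, dict[str, list[float]]] = {}
    callbacks.append(lgb.record_evaluation(evals))
    if X_val is not None:
        Xv, _ = _as_matrix(X_val)
        if not (np.all(np.isfinite(Xv)) and np.all(np.isfinite(y_val))):
            raise ValueError("NaN or infinite values in the validation inputs")
        val_set = lgb.Dataset(Xv, label=np.asarray(y_val, dtype=np.float64),
                              reference=train_set, params={"verbosity": -1})
        valid_sets.append(val_set)
        valid_names.append("val")
        if stopping:
            callbacks.append(lgb.early_stopping(int(stopping), verbose=False))
    booster = lgb.train(p, train_set, num_boost_round=n_rounds,
                        valid_sets=valid_sets, valid_names=valid_names,
                        callbacks=callbacks)
    train_loss = np.asarray(evals.get("train", {}).get("l2", []))
    val_loss = (np.asarray(evals["val"]["l2"]) if "val" in evals else None)
    return DecoderModel(booster, list(names), p, seed, train_loss, val_loss)


def predict(model: DecoderModel, X) -> np.ndarray:
    """One prediction per row; a pure function of (model, X)."""
    Xm, names = _as_matrix(X)
    if names is not None and names != model.feature_names:
        missing = [n for n in model.feature_names if n not in names]
        extra = [n for n in names if n not in model.feature_names]
        if missing or extra:
            raise ValueError(
                f"feature mismatch: missing {missing[:5]}, unexpected {extra[:5]}")
        # same set, different order: realign
        order = [names.index(n) for n in model.feature_names]
        Xm = Xm[:, order]
    if Xm.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, got {Xm.shape[1]}")
    return model.booster.predict(Xm)


def r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot.

    Undefined (raises) for a constant ``y_true``; may be negative when
    the predictions explain less variance than the mean of the truth.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need equal-length series of at least 2 samples")
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R^2 undefined for a constant target")
    ss_res = float(((y_true - y_pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def pearson_r(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Pearson correlation; NaN when either series is constant."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.std() == 0 or y_pred.std() == 0:
        return np.nan
    return float(stats.pearsonr(y_true, y_pred).statistic)


def evaluate(model: DecoderModel, X, y_true: np.ndarray, kind: str = "",
             split: str = "") -> EvalResult:
    """Predict and score one split with R² and Pearson r."""
    y_pred = predict(model, X)
    r = pearson_r(y_true, y_pred)
    return EvalResult(r2=r2_score(y_true, y_pred), pearson_r=r, kind=kind,
                      split=split, constant_prediction=bool(np.std(y_pred) == 0))
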