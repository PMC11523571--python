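"""Shared fixtures: synthetic sessions and fitted pipeline runs.

The expensive end-to-end artifacts (ten default-gain sessions with
fitted fold models, importances and held-out evaluations, plus ten
zero-coupling control sessions) are session-scoped so the recovery,
feature-set-comparison and lag-gradient tests share one computation.

Problem sizes are desk-scale by design: 180 s sessions (896 analysis
windows on the default 1 s / 0.2 s grid) for the coupled runs, 120 s
for the null controls, and a compact decoder (150 trees, learning rate
0.1, early stopping patience 25). docs/methods.md discusses what these
sizes do and do not demonstrate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import defdecode as dd
from defdecode.config import PipelineConfig
from defdecode.decode import predict, r2_score, pearson_r
from defdecode.markers import FeatureMatrix
from defdecode.partition import SplitPlan, make_split
from defdecode.pipeline import fit_final, fold_models, prepare_session
from defdecode.select import (SelectionTrace, aggregate_importance,
                              rank_features, sequential_select, shap_tensor)
from defdecode.synth import Gains, GroundTruth

N_SEEDS = 10
RECOVERY_DURATION_S = 180.0
NULL_DURATION_S = 120.0
TEST_DECODER_PARAMS = {
    "n_estimators": 150,
    "learning_rate": 0.1,
    "early_stopping_rounds": 25,
}
SELECTION_SIZES = np.array([1, 2, 4, 8, 16, 32, 64, 128, 256])


@dataclass
class PipelineRun:
    """One synthetic session taken through the full decoding pipeline."""

    seed: int
    features: FeatureMatrix
    y_jerk: np.ndarray
    y_press: np.ndarray
    split: SplitPlan
    truth: GroundTruth
    z_windows: np.ndarray
    models: list            # per-fold decoders (all features, jerk target)
    importance: "dd.ImportanceVector"
    ranked: list[str]
    tensor: "dd.ShapTensor"
    test_r2_jerk: float
    test_r_jerk: float

    def final_eval(self, names: list[str], y: np.ndarray | None = None
                   ) -> tuple[float, float]:
        """Held-out R² and r for a feature subset (two-stage final fit)."""
        y = self.y_jerk if y is None else y
        pos = {n: i for i, n in enumerate(self.features.names)}
        idx = [pos[n] for n in names]
        model = fit_final(self.features.values[:, idx], y, self.split,
                          TEST_DECODER_PARAMS, self.seed, names)
        te = self.split.test_indices
        pred = predict(model, self.features.values[np.ix_(te, idx)])
        return r2_score(y[te], pred), pearson_r(y[te], pred)


def _run_session(seed: int) -> PipelineRun:
    rec, acc, events, truth = dd.generate_session(seed, RECOVERY_DURATION_S)
    cfg = PipelineConfig(duration_s=RECOVERY_DURATION_S, seed=seed)
    data = prepare_session(rec, cfg, acc, events, None)
    fm = data.features
    y = data.targets["jerk"]
    split = data.split
    models = fold_models(fm, y, split, TEST_DECODER_PARAMS, seed)
    tensor = shap_tensor(
        {(0, f): m for f, m in enumerate(models)},
        {(0, f): fm.values[fold.val_indices]
         for f, fold in enumerate(split.folds)},
    )
    imp = aggregate_importance(tensor)
    final = fit_final(fm.values, y, split, TEST_DECODER_PARAMS, seed, fm.names)
    te = split.test_indices
    pred = predict(final, fm.values[te])
    z_win = dd.window_average(dd.BehaviorSeries(truth.z, "jerk"), fm.grid)
    return PipelineRun(
        seed=seed, features=fm, y_jerk=y, y_press=data.targets["press_rate"],
        split=split, truth=truth, z_windows=z_win, models=models,
        importance=imp, ranked=rank_features(imp), tensor=tensor,
        test_r2_jerk=r2_score(y[te], pred), test_r_jerk=pearson_r(y[te], pred),
    )


@pytest.fixture(scope="session")
def pipeline_runs() -> list[PipelineRun]:
    """Ten seeded default-gain sessions through the full pipeline."""
    return [_run_session(seed) for seed in range(N_SEEDS)]


@pytest.fixture(scope="session")
def null_test_r2() -> list[float]:
    """Held-out jerk R² on ten zero-coupling control sessions."""
    out = []
    cfg = PipelineConfig(duration_s=NULL_DURATION_S)
    for seed in range(N_SEEDS):
        rec, acc, events, _ = dd.generate_session(
            100 + seed, NULL_DURATION_S, gains=Gains(0, 0, 0, 0))
        data = prepare_session(rec, cfg, acc, events, None)
        fm, y, split = data.features, data.targets["jerk"], data.split
        model = fit_final(fm.values, y, split, TEST_DECODER_PARAMS, seed,
                          fm.names)
        te = split.test_indices
        out.append(r2_score(y[te], predict(model, fm.values[te])))
    return out


@pytest.fixture(scope="session")
def selection_traces(pipeline_runs) -> dict[int, SelectionTrace]:
    """Sequential-selection traces (jerk target) for every session."""
    traces = {}
    for run in pipeline_runs:
        fm, y = run.features, run.y_jerk
        pos = {n: i for i, n in enumerate(fm.names)}
        order = [pos[n] for n in run.ranked]
        fd = [(fm.values[f.train_indices][:, order], y[f.train_indices],
               fm.values[f.val_indices][:, order], y[f.val_indices])
              for f in run.split.folds]
        traces[run.seed] = sequential_select(
            run.ranked, fd, TEST_DECODER_PARAMS, run.seed, SELECTION_SIZES)
    return traces


@pytest.fixture(scope="session")
def small_session():
    """One 90 s default-gain session with prepared features (light tests)."""
    rec, acc, events, truth = dd.generate_session(7, 90.0)
    cfg = PipelineConfig(duration_s=90.0, seed=7)
    data = prepare_session(rec, cfg, acc, events, truth.freezing_frames)
    return rec, acc, events, truth, data
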