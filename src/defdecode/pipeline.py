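"""End-to-end orchestration of one decoding run.

The stages mirror the analysis flow: preprocess → behavior targets →
marker extraction → chronological partitioning → per-fold decoding →
SHAP importance → sequential selection → final evaluation on the
held-out tail of the session.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from . import behavior as bh
from . import io as dio
from .config import PipelineConfig
from .decode import DecoderModel, EvalResult, evaluate, fit_decoder, predict, r2_score
from .markers import FeatureConfig, FeatureMatrix, extract_feature_matrix
from .partition import SplitPlan, make_split
from .preprocess import (BandSet, Recording, band_decompose, clean_broadband,
                         make_window_grid, mark_artifacts, multitaper_csd)
from .select import (ImportanceVector, SelectionTrace, aggregate_importance,
                     rank_features, sequential_select, shap_tensor)
from .synth import generate_session

__all__ = [
    "SessionData",
    "SessionResult",
    "prepare_session",
    "fold_models",
    "session_importance",
    "decode_session",
    "run_pipeline",
    "compare_feature_sets",
]


@dataclass
class SessionData:
    """Preprocessed inputs for one session: features and behavior targets."""

    features: FeatureMatrix
    targets: dict[str, np.ndarray]  # behavior kind -> window-averaged values
    split: SplitPlan
    recording: Recording


def _feature_config(cfg: PipelineConfig) -> FeatureConfig:
    kw: dict = {
        "symmetric_combinations": cfg.features.symmetric_combinations,
        "entropy_m": cfg.features.entropy_m,
        "entropy_r_factor": cfg.features.entropy_r_factor,
    }
    if cfg.features.families is not None:
        kw["families"] = tuple(cfg.features.families)
    return FeatureConfig(**kw)


def prepare_session(rec: Recording, cfg: PipelineConfig,
                    acc: bh.AccelerometryTrace | None = None,
                    events: bh.EventTrain | None = None,
                    freezing_frames: np.ndarray | None = None) -> SessionData:
    """Preprocess, extract the feature matrix and window-average behaviors."""
    bands = BandSet(tuple(cfg.bands)) if cfg.bands else BandSet()
    f = cfg.filter
    clean = clean_broadband(rec, f.line_freq_hz, (f.band_low_hz, f.band_high_hz),
                            f.order, f.notch_q)
    if cfg.artifacts.enabled:
        clean = mark_artifacts(clean, cfg.artifacts.z_thresh, cfg.artifacts.pad_s)
    dec = band_decompose(clean, bands, f.order)
    grid = make_window_grid(clean.n_samples, clean.fs,
                            cfg.window.length_s, cfg.window.step_s)
    if cfg.artifacts.enabled:
        grid = grid.drop_artifact_windows(clean.artifact_mask)

    fc = _feature_config(cfg)
    cs = None
    if "Coh" in fc.families:
        il = clean.channels_in_region("IL")
        bla = clean.channels_in_region("BLA")
        pairs = [(m, n) for m in il for n in bla]
        cs = multitaper_csd(clean, pairs, grid, fmin=f.band_low_hz,
                            fmax=f.band_high_hz)
    fm = extract_feature_matrix(clean, dec, cs, grid, fc)
    if cfg.features.lag_steps != [0]:
        from .select import lag_augment

        fm = lag_augment(fm, cfg.features.lag_steps)
        grid = fm.grid

    targets: dict[str, np.ndarray] = {}
    duration = clean.duration_s
    if acc is not None:
        targets["jerk"] = bh.window_average(bh.accelerometry_jerk(acc), grid)
    if events is not None:
        targets["press_rate"] = bh.window_average(
            bh.bar_press_rate(events, duration), grid)
    if freezing_frames is not None:
        targets["freezing"] = bh.window_average(
            bh.freezing_series(freezing_frames, duration_s=duration), grid)

    split = make_split(fm.n_windows, cfg.split.test_fraction,
                       cfg.split.purge_gap_windows)
    return SessionData(fm, targets, split, clean)


def fit_final(X: np.ndarray, y: np.ndarray, split: SplitPlan,
              params: dict | None, seed: int,
              feature_names: list[str] | None = None) -> DecoderModel:
    """Fit the test-set model on the train+val prefix, leak-free.

    The boosting-round count is chosen chronologically: a first model is
    early-stopped on the final validation block (the latest pre-test
    data), and the returned model is refit on the whole train+val prefix
    with that round count. Without this, a model with many uninformative
    features overfits and its held-out R² is dominated by noise.
    """
    last = split.folds[-1]
    tv = split.trainval_indices
    pre = tv[tv < last.val_indices[0]]
    stage1 = fit_decoder(X[pre], y[pre], params, seed=seed,
                         X_val=X[last.val_indices], y_val=y[last.val_indices],
                         feature_names=feature_names)
    n_rounds = max(1, stage1.booster.best_iteration or
                   stage1.booster.current_iteration())
    p = dict(params or {})
    p["n_estimators"] = n_rounds
    p["early_stopping_rounds"] = 0
    return fit_decoder(X[tv], y[tv], p, seed=seed, feature_names=feature_names)


def fold_models(fm: FeatureMatrix, y: np.ndarray, split: SplitPlan,
                params: dict | None, seed: int) -> list[DecoderModel]:
    """Train one decoder per chronological fold (validation early stopping)."""
    models = []
    for fold in split.folds:
        models.append(fit_decoder(
            fm.values[fold.train_indices], y[fold.train_indices], params,
            seed=seed, X_val=fm.values[fold.val_indices],
            y_val=y[fold.val_indices], feature_names=fm.names))
    return models


def session_importance(fm: FeatureMatrix, y: np.ndarray, split: SplitPlan,
                       params: dict | None, seed: int,
                       shap_on: str = "val") -> ImportanceVector:
    """Fold-wise SHAP attributions aggregated into one importance vector."""
    models = fold_models(fm, y, split, params, seed)
    X = {}
    mdl = {}
    for f, (fold, model) in enumerate(zip(split.folds, models)):
        if shap_on == "val":
            idx = fold.val_indices
        elif shap_on == "train":
            idx = fold.train_indices
        else:
            idx = np.concatenate([fold.train_indices, fold.val_indices])
        mdl[(0, f)] = model
        X[(0, f)] = fm.values[idx]
    return aggregate_importance(shap_tensor(mdl, X))


@dataclass
class SessionResult:
    """Everything a run emits for one behavior target."""

    behavior: str
    importance: ImportanceVector
    trace: SelectionTrace | None
    metrics: dict

    def metrics_json(self) -> str:
        return json.dumps(self.metrics, indent=2, sort_keys=True)


def decode_session(data: SessionData, behavior_kind: str,
                   cfg: PipelineConfig) -> SessionResult:
    """Importance, selection, and test-set evaluation for one behavior."""
    fm = data.features
    y = data.targets[behavior_kind]
    split = data.split
    params = cfg.decoder.to_params()
    seed = cfg.seed

    imp = session_importance(fm, y, split, params, seed,
                             cfg.selection.shap_on)
    ranked = rank_features(imp)

    names = fm.names
    pos = {n: i for i, n in enumerate(names)}

    trace = None
    if cfg.selection.enabled:
        rank_idx = [pos[n] for n in ranked]
        fd = [(fm.values[f.train_indices][:, rank_idx], y[f.train_indices],
               fm.values[f.val_indices][:, rank_idx], y[f.val_indices])
              for f in split.folds]
        sizes = (np.array(cfg.selection.sizes)
                 if cfg.selection.sizes else None)
        trace = sequential_select(ranked, fd, params, seed, sizes,
                                  cfg.selection.alpha)

    # final models trained on the full train+val prefix, scored on the test tail
    def final_eval(subset: list[str], label: str) -> EvalResult:
        idx = [pos[n] for n in subset]
        model = fit_final(fm.values[:, idx], y, split, params, seed,
                          feature_names=subset)
        te = split.test_indices
        return evaluate(model, fm.values[np.ix_(te, idx)], y[te],
                        kind=behavior_kind, split=label)

    res_all = final_eval(names, "test:all")
    metrics = {
        "behavior": behavior_kind,
        "n_windows": int(fm.n_windows),
        "n_features": int(fm.n_features),
        "test_r2_all": res_all.r2,
        "test_r_all": res_all.pearson_r,
    }
    if trace is not None:
        res_sel = final_eval(trace.selected, "test:selected")
        metrics.update({
            "n_selected": int(trace.i_star),
            "val_r2_max": trace.r2_max,
            "test_r2_selected": res_sel.r2,
            "test_r_selected": res_sel.pearson_r,
        })
    bp_names = [n for n in fm.names if n.startswith("BP|")]
    if bp_names:
        res_bp = final_eval(bp_names, "test:bp")
        metrics.update({"test_r2_bp": res_bp.r2, "test_r_bp": res_bp.pearson_r})
    return SessionResult(behavior_kind, imp, trace, metrics)


def run_pipeline(cfg: PipelineConfig, out_dir) -> Path:
    """Execute the full pipeline and write the run directory.

    Emits metrics.json, importance.csv, selection.json (when selection is
    enabled), qc.json and the resolved configuration. Deterministic:
    re-running with the same configuration reproduces the files
    byte-for-byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.simulate or cfg.bundle is None:
        rec, acc, events, truth = generate_session(cfg.seed, cfg.duration_s)
        freezing = truth.freezing_frames
    else:
        rec, acc = dio.load_bundle(cfg.bundle)
        events = dio.load_events_csv(cfg.events) if cfg.events else None
        freezing = dio.load_freezing_csv(cfg.freezing) if cfg.freezing else None

    data = prepare_session(rec, cfg, acc, events, freezing)
    if cfg.behavior not in data.targets:
        raise ValueError(
            f"behavior {cfg.behavior!r} requested but its raw inputs are missing")
    result = decode_session(data, cfg.behavior, cfg)

    (out / "metrics.json").write_text(result.metrics_json())
    imp = result.importance
    order = imp.ranking()
    lines = ["feature,importance"]
    lines += [f"{imp.feature_names[i]},{imp.imp[i]:.10g}" for i in order]
    (out / "importance.csv").write_text("\n".join(lines) + "\n")
    if result.trace is not None:
        (out / "selection.json").write_text(result.trace.to_json())
    (out / "qc.json").write_text(json.dumps(
        {"imputed_by_family": data.features.qc,
         "n_windows": int(data.features.n_windows),
         "n_features": int(data.features.n_features)},
        indent=2, sort_keys=True))
    cfg.to_yaml(out / "resolved_config.yaml")
    return out


def compare_feature_sets(results: dict[str, list[float]],
                         alpha: float = 0.05) -> dict:
    """Paired Wilcoxon signed-rank comparison of decoding conditions.

    ``results`` maps a condition label (e.g. "bp", "selected", "all") to
    paired per-subject/per-seed performance values. P-values are
    Bonferroni-corrected by the number of condition pairs.
    """
    labels = sorted(results)
    n = {k: len(v) for k, v in results.items()}
    if len(set(n.values())) != 1:
        raise ValueError(f"unpaired runs: condition sizes {n}")
    if next(iter(n.values())) < 6:
        raise ValueError("need at least 6 paired runs")
    pairs = list(itertools.combinations(labels, 2))
    comparisons = {}
    for a, b in pairs:
        x = np.asarray(results[a], dtype=float)
        yv = np.asarray(results[b], dtype=float)
        if np.allclose(x, yv):
            p = 1.0
        else:
            p = float(stats.wilcoxon(x, yv).pvalue)
        p_corr = min(1.0, p * len(pairs))
        comparisons[f"{a}_vs_{b}"] = {
            "p": p, "p_bonferroni": p_corr,
            "significant": p_corr < alpha,
            "mean_diff": float(np.mean(x) - np.mean(yv)),
        }
    return {
        "means": {k: float(np.mean(v)) for k, v in results.items()},
        "comparisons": comparisons,
    }
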