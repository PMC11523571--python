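"""Shapley-value feature importance, ranking, and sequential selection.

Feature attributions are exact tree-path Shapley values from the fitted
GBDT ensembles (LightGBM's native TreeSHAP). Per-feature importance is
the mean absolute attribution over validation instances, the 5
chronological folds, and recording sessions:

    imp_i = 1/(5·N·S) · Σ_s Σ_f Σ_n |φ_{n,f,s,i}|

Features are ranked by imp_i; models are re-trained on growing top-i
subsets; a paired t-test between each subset's 5 fold validation R²
values and the peak size's values stops the search at the smallest
subset whose performance is statistically indistinguishable from the
peak (p ≥ 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from scipy import stats

from .decode import DecoderModel, fit_decoder, predict, r2_score
from .markers import FeatureDescriptor, FeatureMatrix

__all__ = [
    "ShapTensor",
    "ImportanceVector",
    "SelectionTrace",
    "shap_tensor",
    "aggregate_importance",
    "rank_features",
    "default_size_grid",
    "sequential_select",
    "pooled_selection_size",
    "removal_contribution",
    "band_significance",
    "importance_similarity",
    "lag_augment",
    "paired_ttest_pvalue",
]


@dataclass
class ShapTensor:
    """Per-instance Shapley attributions φ[n, f, s, i].

    Stored as one (N_sf, M) array per (session, fold) cell so that folds
    whose validation blocks differ by one window remain representable.
    ``base_values`` and ``predictions`` allow the local-accuracy check
    Σ_i φ + base = prediction.
    """

    phi: dict[tuple[int, int], np.ndarray]  # (session, fold) -> (N, M)
    base_values: dict[tuple[int, int], np.ndarray]
    predictions: dict[tuple[int, int], np.ndarray]
    feature_names: list[str]

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def local_accuracy_error(self) -> float:
        """Max relative |Σφ + base − prediction| across all instances."""
        worst = 0.0
        for key, phi in self.phi.items():
            recon = phi.sum(axis=1) + self.base_values[key]
            pred = self.predictions[key]
            scale = max(1e-12, float(np.abs(pred).max()))
            worst = max(worst, float(np.abs(recon - pred).max()) / scale)
        return worst


@dataclass
class ImportanceVector:
    """Non-negative per-feature importance imp_i."""

    imp: np.ndarray
    feature_names: list[str]

    def ranking(self) -> np.ndarray:
        """Feature indices by decreasing importance; name order breaks ties."""
        order = np.lexsort((self.feature_names, -self.imp))
        return order

    def top(self, k: int) -> list[str]:
        return [self.feature_names[i] for i in self.ranking()[:k]]


@dataclass
class SelectionTrace:
    """Validation-R² curve over subset sizes and the selected subset."""

    sizes: np.ndarray
    fold_r2: np.ndarray          # (n_sizes, 5)
    mean_r2: np.ndarray
    p_values: np.ndarray
    r2_max: float
    argmax_size: int
    i_star: int
    selected: list[str]

    def to_json(self) -> str:
        import json

        return json.dumps({
            "sizes": self.sizes.tolist(),
            "mean_r2": np.round(self.mean_r2, 10).tolist(),
            "p_values": [None if not np.isfinite(p) else float(p)
                         for p in self.p_values],
            "r2_max": self.r2_max,
            "argmax_size": int(self.argmax_size),
            "i_star": int(self.i_star),
            "selected": self.selected,
        }, indent=2)


def shap_tensor(models: Mapping[tuple[int, int], DecoderModel],
                X: Mapping[tuple[int, int], Any]) -> ShapTensor:
    """Exact tree-path Shapley attributions per (session, fold) instance set.

    ``models[(s, f)]`` is the fold-f model of session s and ``X[(s, f)]``
    the instances (typically that fold's validation windows) to attribute.
    """
    phi: dict[tuple[int, int], np.ndarray] = {}
    base: dict[tuple[int, int], np.ndarray] = {}
    preds: dict[tuple[int, int], np.ndarray] = {}
    names: list[str] | None = None
    for key, model in models.items():
        if names is None:
            names = model.feature_names
        elif names != model.feature_names:
            raise ValueError("models disagree on the feature set")
        Xm = X[key].values if isinstance(X[key], FeatureMatrix) else np.asarray(X[key])
        if Xm.shape[1] != len(names):
            raise ValueError("instance matrix does not match the model features")
        contrib = model.booster.predict(Xm, pred_contrib=True)
        phi[key] = contrib[:, :-1]
        base[key] = contrib[:, -1]
        preds[key] = model.booster.predict(Xm)
    if names is None:
        raise ValueError("no models given")
    return ShapTensor(phi, base, preds, list(names))


def aggregate_importance(tensor: ShapTensor) -> ImportanceVector:
    """Mean |φ| over instances, folds and sessions.

    Equals the flat 1/(5NS) triple sum when every (session, fold) cell
    has the same instance count, and degrades to the mean of per-cell
    means otherwise.
    """
    cells = [np.abs(phi).mean(axis=0) for phi in tensor.phi.values()]
    if not cells:
        raise ValueError("empty tensor")
    imp = np.mean(cells, axis=0)
    return ImportanceVector(imp, tensor.feature_names)


def rank_features(imp: ImportanceVector) -> list[str]:
    return [imp.feature_names[i] for i in imp.ranking()]


def default_size_grid(n_features: int) -> np.ndarray:
    """Subset sizes to evaluate: 1..30, every 5th to 100, every 25th to M."""
    sizes = list(range(1, min(31, n_features + 1)))
    sizes += list(range(35, min(101, n_features + 1), 5))
    sizes += list(range(125, n_features + 1, 25))
    if n_features not in sizes:
        sizes.append(n_features)
    return np.array(sorted(set(sizes)))


def paired_ttest_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Paired-sample t-test p-value; identical/zero-variance pairs give 1."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if np.allclose(a, b):
        return 1.0
    d = a - b
    if np.std(d, ddof=1) == 0:
        return 1.0
    return float(stats.ttest_rel(a, b).pvalue)


def sequential_select(ranked_names: Sequence[str],
                      fold_data: Sequence[tuple],
                      params: dict | None = None,
                      seed: int = 0,
                      sizes: np.ndarray | None = None,
                      alpha: float = 0.05) -> SelectionTrace:
    """Grow the feature set in ranking order; stop at statistical parity.

    Parameters
    ----------
    ranked_names : sequence of str
        Features in decreasing importance order.
    fold_data : sequence of (X_train, y_train, X_val, y_val)
        One tuple per chronological fold. FeatureMatrix inputs are
        re-ordered by name to match ``ranked_names``; plain arrays must
        already have their columns in ranking order.
    sizes : array, optional
        Evaluation grid of subset sizes (default: 1..30, every 5th to
        100, every 25th to M).

    For each size i, a model per fold is trained on the top-i features
    and scored on its validation windows; R²_max is the peak fold-mean;
    i* is the smallest size whose 5 fold R² values are not significantly
    below the peak size's (paired t-test, p ≥ alpha).
    """
    M = len(ranked_names)
    if M < 2:
        raise ValueError("need at least 2 ranked features")
    sizes = default_size_grid(M) if sizes is None else np.asarray(sizes)
    sizes = sizes[(sizes >= 1) & (sizes <= M)]

    prepared = []
    for X_tr, y_tr, X_va, y_va in fold_data:
        if isinstance(X_tr, FeatureMatrix):
            order = [X_tr.names.index(n) for n in ranked_names]
            Xt, Xv = X_tr.values[:, order], X_va.values[:, order]
        else:
            Xt, Xv = np.asarray(X_tr), np.asarray(X_va)
        prepared.append((Xt, np.asarray(y_tr), Xv, np.asarray(y_va)))

    fold_r2 = np.full((len(sizes), len(prepared)), np.nan)
    kept_sizes = []
    for si, size in enumerate(sizes):
        cols = list(ranked_names[:size])
        for fi, (Xt, yt, Xv, yv) in enumerate(prepared):
            model = fit_decoder(Xt[:, :size], yt, params, seed=seed,
                                X_val=Xv[:, :size], y_val=yv,
                                feature_names=cols)
            fold_r2[si, fi] = r2_score(yv, predict(model, Xv[:, :size]))
        kept_sizes.append(size)
    valid = ~np.all(np.isnan(fold_r2), axis=1)
    sizes, fold_r2 = sizes[valid], fold_r2[valid]
    mean_r2 = fold_r2.mean(axis=1)
    best = int(np.argmax(mean_r2))
    r2_max = float(mean_r2[best])
    p_values = np.array([
        paired_ttest_pvalue(fold_r2[si], fold_r2[best]) for si in range(len(sizes))
    ])
    ok = np.where(p_values >= alpha)[0]
    i_star = int(sizes[ok[0]]) if len(ok) else int(sizes[best])
    return SelectionTrace(sizes, fold_r2, mean_r2, p_values, r2_max,
                          int(sizes[best]), i_star,
                          list(ranked_names[:i_star]))


def pooled_selection_size(sizes: np.ndarray, run_mean_r2: np.ndarray,
                          alpha: float = 0.05) -> tuple[int, np.ndarray, int]:
    """Population-level subset size across runs (subjects/sessions/seeds).

    At each candidate size the per-run mean validation R² values are
    paired against the peak size's values (paired t-test across runs);
    the selected size is the smallest whose performance is statistically
    indistinguishable from the peak (p ≥ alpha). This is the
    across-subject form of the stopping rule — a single subset size for
    the whole population — as opposed to the per-session, fold-paired
    form in :func:`sequential_select`.

    Parameters
    ----------
    sizes : (n_sizes,) array
        The common evaluation grid.
    run_mean_r2 : (n_runs, n_sizes) array
        Fold-mean validation R² per run and size.

    Returns
    -------
    (i_star, p_values, argmax_size)
    """
    sizes = np.asarray(sizes)
    A = np.asarray(run_mean_r2, dtype=float)
    if A.ndim != 2 or A.shape[1] != len(sizes):
        raise ValueError("run_mean_r2 must be (n_runs, n_sizes)")
    grand = A.mean(axis=0)
    best = int(np.argmax(grand))
    p_values = np.array([paired_ttest_pvalue(A[:, i], A[:, best])
                         for i in range(len(sizes))])
    ok = np.where(p_values >= alpha)[0]
    i_star = int(sizes[ok[0]]) if len(ok) else int(sizes[best])
    return i_star, p_values, int(sizes[best])


def removal_contribution(X: FeatureMatrix, y: np.ndarray,
                         fold_data: Sequence[tuple],
                         groups: Mapping[str, Sequence[str]],
                         params: dict | None = None,
                         seed: int = 0) -> dict[str, float]:
    """ΔR² from excluding each feature group from the model input.

    ΔR² = fold-mean validation R²(all features) − R²(all minus group).
    ``groups`` maps a group label (family, band, family x band...) to the
    feature names it contains.
    """
    names = X.names

    def fold_mean_r2(col_idx: np.ndarray) -> float:
        vals = []
        for tr_idx, va_idx in fold_data:
            model = fit_decoder(X.values[np.ix_(tr_idx, col_idx)], y[tr_idx],
                                params, seed=seed,
                                X_val=X.values[np.ix_(va_idx, col_idx)],
                                y_val=y[va_idx],
                                feature_names=[names[i] for i in col_idx])
            vals.append(r2_score(y[va_idx],
                                 predict(model, X.values[np.ix_(va_idx, col_idx)])))
        return float(np.mean(vals))

    all_idx = np.arange(len(names))
    base = fold_mean_r2(all_idx)
    out: dict[str, float] = {}
    for label, members in groups.items():
        member_set = set(members)
        keep = np.array([i for i, n in enumerate(names) if n not in member_set])
        if len(keep) == 0:
            raise ValueError(f"group {label!r} covers every feature column")
        if len(keep) == len(names):
            out[label] = 0.0
            continue
        out[label] = base - fold_mean_r2(keep)
    return out


def band_significance(values_by_band: Mapping[str, np.ndarray], band: str,
                      n_comparisons: int | None = None) -> dict[str, float]:
    """Independent t-test of one band's importances vs. all other bands pooled.

    Bonferroni-corrects by the number of bands tested (defaults to the
    number of bands present). Raises on degenerate (zero-variance
    identical) groups.
    """
    if band not in values_by_band:
        raise KeyError(f"band {band!r} not present")
    a = np.asarray(values_by_band[band], dtype=float)
    b = np.concatenate([np.asarray(v, dtype=float)
                        for k, v in values_by_band.items() if k != band])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        raise ValueError("zero variance in both groups; t-test undefined")
    t, p = stats.ttest_ind(a, b)
    k = n_comparisons if n_comparisons is not None else len(values_by_band)
    p_corr = min(1.0, float(p) * k)
    return {"t": float(t), "p": float(p), "p_bonferroni": p_corr,
            "significant": p_corr < 0.05}


def importance_similarity(A: np.ndarray, B: np.ndarray) -> tuple[float, float]:
    """Pearson r and p over the flattened paired elements of two matrices."""
    A, B = np.asarray(A, dtype=float), np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("importance matrices must share a shape")
    res = stats.pearsonr(A.ravel(), B.ravel())
    return float(res.statistic), float(res.pvalue)


def lag_augment(X: FeatureMatrix, lag_steps: Sequence[int]) -> FeatureMatrix:
    """Append time-lagged copies of every feature column.

    ``lag_steps`` are non-negative window-step counts (0 = the current
    window). Initial windows lacking the full history are dropped, so
    the output has n_windows − max(lag) rows and n_features × len(lags)
    columns. Lag 0 with no other lags returns the matrix unchanged.
    """
    lags = sorted(set(int(l) for l in lag_steps))
    if any(l < 0 for l in lags):
        raise ValueError("lags must be non-negative")
    if lags == [0]:
        return X
    L = max(lags)
    if L >= X.n_windows:
        raise ValueError("lag exceeds the session length")
    cols = []
    descs: list[FeatureDescriptor] = []
    for lag in lags:
        sl = slice(L - lag, X.n_windows - lag)
        cols.append(X.values[sl])
        for d in X.descriptors:
            descs.append(FeatureDescriptor(d.family, d.channels, d.bands,
                                           d.direction, lag))
    grid = None
    if X.grid is not None:
        from dataclasses import replace

        grid = replace(X.grid, start_indices=X.grid.start_indices[L:])
    return FeatureMatrix(np.column_stack(cols), descs, grid, dict(X.qc))
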