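"""Chronology-preserving dataset partitioning.

The final 20% of analysis windows form a held-out test set. The leading
80% is divided evenly into 9 chronological blocks; fold k (k = 1..5)
trains on blocks k..k+3 and validates on block k+4, sliding one block
forward per fold. The model is therefore always trained on data that
precedes its validation data, and the train:val and (train+val):test
ratios are 4:1 and 80:20.
"""

from __future__ import annotations

from dataclasses import dataclass

import json
import numpy as np

__all__ = ["Fold", "SplitPlan", "make_split"]

N_BLOCKS = 9
N_FOLDS = 5
TRAIN_BLOCKS = 4


@dataclass(frozen=True)
class Fold:
    train_indices: np.ndarray
    val_indices: np.ndarray


@dataclass(frozen=True)
class SplitPlan:
    """Held-out test range plus 5 sliding chronological train/val folds."""

    test_indices: np.ndarray
    folds: tuple[Fold, ...]
    n_windows: int

    @property
    def trainval_indices(self) -> np.ndarray:
        return np.arange(self.n_windows - len(self.test_indices))

    def to_json(self) -> str:
        return json.dumps({
            "n_windows": self.n_windows,
            "test": [int(self.test_indices[0]), int(self.test_indices[-1]) + 1],
            "folds": [
                {
                    "train": [int(f.train_indices[0]), int(f.train_indices[-1]) + 1],
                    "val": [int(f.val_indices[0]), int(f.val_indices[-1]) + 1],
                }
                for f in self.folds
            ],
        })


def _block_sizes(n: int) -> list[int]:
    """Sizes of the 9 chronological blocks; earliest blocks absorb the remainder."""
    base, extra = divmod(n, N_BLOCKS)
    return [base + 1 if i < extra else base for i in range(N_BLOCKS)]


def make_split(n_windows: int, test_fraction: float = 0.2,
               purge_gap_windows: int = 0) -> SplitPlan:
    """Build the sliding-window 5-fold chronological split.

    Parameters
    ----------
    n_windows : int
        Total number of analysis windows (>= 45 so every block is
        non-empty).
    test_fraction : float
        Fraction of windows held out at the end of the session.
    purge_gap_windows : int
        Optionally drop this many windows on each side of every
        train/validation boundary, removing overlapping-window sample
        sharing across the boundary (off by default, matching the plain
        scheme).
    """
    min_n = int(np.ceil(N_BLOCKS / (1 - test_fraction)))
    if n_windows < max(min_n, 45):
        raise ValueError(
            f"need at least {max(min_n, 45)} windows for a 9-block split, got {n_windows}"
        )
    n_test = int(np.floor(test_fraction * n_windows))
    prefix = n_windows - n_test
    sizes = _block_sizes(prefix)
    edges = np.concatenate([[0], np.cumsum(sizes)])
    folds = []
    for k in range(N_FOLDS):
        train = np.arange(edges[k], edges[k + TRAIN_BLOCKS])
        val = np.arange(edges[k + TRAIN_BLOCKS], edges[k + TRAIN_BLOCKS + 1])
        if purge_gap_windows > 0:
            g = purge_gap_windows
            boundary = edges[k + TRAIN_BLOCKS]
            train = train[train < boundary - g]
            val = val[val >= boundary + g]
            if not len(train) or not len(val):
                raise ValueError("purge gap leaves an empty train or val block")
        folds.append(Fold(train, val))
    test = np.arange(prefix, n_windows)
    return SplitPlan(test, tuple(folds), n_windows)
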