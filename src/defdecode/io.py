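"""Reading and writing the signal bundles and event tables.

Signal bundles are HDF5 or NPZ files with datasets ``lfp``
(channels x samples), ``fs``, ``labels``, ``regions`` and optionally
``acc`` (3 x samples) with ``acc_fs``. Bar-press events are CSV with a
``timestamp_s`` column; freezing scores are CSV with ``frame`` and
``score`` columns.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .behavior import AccelerometryTrace, EventTrain
from .preprocess import Recording

__all__ = [
    "save_bundle",
    "load_bundle",
    "save_events_csv",
    "load_events_csv",
    "save_freezing_csv",
    "load_freezing_csv",
]


def save_bundle(path, rec: Recording, acc: AccelerometryTrace | None = None
                ) -> None:
    """Write a signal bundle; the extension picks HDF5 (.h5) or NPZ (.npz)."""
    path = Path(path)
    labels = np.array(rec.channel_labels, dtype="S")
    regions = np.array([rec.region_of[c] for c in rec.channel_labels], dtype="S")
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.create_dataset("lfp", data=rec.samples)
            f.create_dataset("fs", data=rec.fs)
            f.create_dataset("labels", data=labels)
            f.create_dataset("regions", data=regions)
            f.create_dataset("artifact_mask", data=rec.artifact_mask)
            if acc is not None:
                f.create_dataset("acc", data=np.vstack([acc.v_x, acc.v_y, acc.v_z]))
                f.create_dataset("acc_fs", data=acc.fs)
    elif path.suffix == ".npz":
        data = {"lfp": rec.samples, "fs": rec.fs, "labels": labels,
                "regions": regions, "artifact_mask": rec.artifact_mask}
        if acc is not None:
            data["acc"] = np.vstack([acc.v_x, acc.v_y, acc.v_z])
            data["acc_fs"] = acc.fs
        np.savez(path, **data)
    else:
        raise ValueError(f"unsupported bundle extension {path.suffix!r}")


def load_bundle(path) -> tuple[Recording, AccelerometryTrace | None]:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            data = {k: f[k][()] for k in f.keys()}
    elif path.suffix == ".npz":
        with np.load(path) as f:
            data = {k: f[k] for k in f.files}
    else:
        raise ValueError(f"unsupported bundle extension {path.suffix!r}")
    labels = [s.decode() if isinstance(s, bytes) else str(s)
              for s in data["labels"]]
    regions_list = [s.decode() if isinstance(s, bytes) else str(s)
                    for s in data["regions"]]
    rec = Recording(
        data["lfp"], float(data["fs"]), labels,
        dict(zip(labels, regions_list)),
        data.get("artifact_mask"),
    )
    acc = None
    if "acc" in data:
        a = data["acc"]
        acc = AccelerometryTrace(a[0], a[1], a[2], float(data["acc_fs"]))
    return rec, acc


def save_events_csv(path, events: EventTrain) -> None:
    pd.DataFrame({"timestamp_s": events.timestamps}).to_csv(path, index=False)


def load_events_csv(path) -> EventTrain:
    df = pd.read_csv(path)
    if "timestamp_s" not in df.columns:
        raise ValueError("events CSV needs a 'timestamp_s' column")
    return EventTrain(df["timestamp_s"].to_numpy())


def save_freezing_csv(path, scores: np.ndarray) -> None:
    pd.DataFrame({"frame": np.arange(len(scores)), "score": scores}
                 ).to_csv(path, index=False)


def load_freezing_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("frame", "score"):
        if col not in df.columns:
            raise ValueError(f"freezing CSV needs a {col!r} column")
    return df.sort_values("frame")["score"].to_numpy(dtype=float)
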