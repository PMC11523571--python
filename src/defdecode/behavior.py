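"""Continuous behavior targets on a 1 kHz grid.

Three defensive-behavior readouts are supported: accelerometry jerk (the
absolute rate of change of 3-axis acceleration magnitude), bar-press rate
(Gaussian-smoothed 1 ms event counts), and an externally supplied
per-video-frame freezing score. All are expressed at 1000 samples/s and
averaged onto the analysis window grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import WindowGrid

__all__ = [
    "AccelerometryTrace",
    "EventTrain",
    "BehaviorSeries",
    "gaussian_kernel",
    "accelerometry_jerk",
    "bar_press_rate",
    "freezing_series",
    "window_average",
]

TARGET_FS = 1000.0


@dataclass
class AccelerometryTrace:
    """3-axis accelerometer voltages (native rate 30 kHz; synthetic 1 kHz)."""

    v_x: np.ndarray
    v_y: np.ndarray
    v_z: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.v_x = np.asarray(self.v_x, dtype=np.float64)
        self.v_y = np.asarray(self.v_y, dtype=np.float64)
        self.v_z = np.asarray(self.v_z, dtype=np.float64)
        if not (len(self.v_x) == len(self.v_y) == len(self.v_z)):
            raise ValueError("accelerometer axes must have equal lengths")
        if not all(np.all(np.isfinite(v)) for v in (self.v_x, self.v_y, self.v_z)):
            raise ValueError("accelerometer voltages must be finite")


@dataclass
class EventTrain:
    """Sorted bar-press timestamps in seconds."""

    timestamps: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=np.float64)
        if t.size and t.min() < 0:
            raise ValueError("negative event timestamp")
        self.timestamps = np.unique(t)


@dataclass
class BehaviorSeries:
    """A continuous behavior readout at 1 kHz."""

    values: np.ndarray
    kind: str  # {"jerk", "press_rate", "freezing"}
    fs: float = TARGET_FS


def gaussian_kernel(n: int) -> np.ndarray:
    """Truncated Gaussian kernel of length ``n``, sigma = n/6, unit sum.

    A Gaussian window of N samples is read as +/-3 sigma support.
    """
    x = np.arange(n) - (n - 1) / 2.0
    sigma = n / 6.0
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _smooth(x: np.ndarray, n: int) -> np.ndarray:
    k = gaussian_kernel(n)
    # zero-padded 'same' convolution
    return np.convolve(x, k, mode="same")


def accelerometry_jerk(acc: AccelerometryTrace, smooth_window: int = 200
                       ) -> BehaviorSeries:
    """j(t) = |d/dt sqrt(Vx^2 + Vy^2 + Vz^2)|, downsampled and smoothed.

    The derivative is a forward first difference scaled by the native
    sampling rate (length preserved by edge replication), computed at the
    native rate, then decimated to 1 kHz, then Gaussian-smoothed with a
    200-sample window.
    """
    if len(acc.v_x) < 2:
        raise ValueError("need at least 2 samples")
    mag = np.sqrt(acc.v_x**2 + acc.v_y**2 + acc.v_z**2)
    d = np.abs(np.diff(mag)) * acc.fs
    d = np.concatenate([d, d[-1:]])  # edge replication keeps length
    factor = acc.fs / TARGET_FS
    if factor != int(factor) or factor < 1:
        raise ValueError(f"fs={acc.fs} is not an integer multiple of 1 kHz")
    d = d[:: int(factor)]  # plain decimation, no pre-filter
    return BehaviorSeries(_smooth(d, smooth_window), "jerk")


def bar_press_rate(events: EventTrain, duration_s: float,
                   smooth_window: int = 1000) -> BehaviorSeries:
    """Bin press counts into 1 ms intervals; smooth with a 1000-sample Gaussian.

    The smoothed series approximates a continuous press rate; total area
    equals the event count away from the edges.
    """
    t = events.timestamps
    if t.size and duration_s < t.max():
        raise ValueError("duration shorter than the last event timestamp")
    n = int(round(duration_s * TARGET_FS))
    bins = np.zeros(n)
    if t.size:
        # epsilon guards against fp timestamps landing one bin early
        ix = np.minimum(np.floor(t * TARGET_FS + 1e-9).astype(np.int64), n - 1)
        np.add.at(bins, ix, 1.0)
    return BehaviorSeries(_smooth(bins, smooth_window), "press_rate")


def freezing_series(frame_scores: np.ndarray, frame_rate: float = 24.0,
                    duration_s: float | None = None) -> BehaviorSeries:
    """Linearly interpolate a per-frame freezing score to the 1 kHz grid."""
    scores = np.asarray(frame_scores, dtype=np.float64)
    if scores.ndim != 1 or scores.size < 2:
        raise ValueError("need a 1-D series of at least 2 frame scores")
    frame_t = np.arange(scores.size) / frame_rate
    if duration_s is None:
        duration_s = scores.size / frame_rate
    t = np.arange(int(round(duration_s * TARGET_FS))) / TARGET_FS
    return BehaviorSeries(np.interp(t, frame_t, scores), "freezing")


def window_average(series: BehaviorSeries, grid: WindowGrid) -> np.ndarray:
    """Arithmetic mean of the 1 kHz series inside each analysis window."""
    if grid.fs != series.fs:
        raise ValueError("window grid and behavior series sampling rates differ")
    last = grid.start_indices.max() + grid.window_length if grid.n_windows else 0
    if last > len(series.values):
        raise ValueError("window grid extends past the behavior series")
    c = np.concatenate([[0.0], np.cumsum(series.values)])
    s = grid.start_indices
    return (c[s + grid.window_length] - c[s]) / grid.window_length
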