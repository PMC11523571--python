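"""Synthetic sessions with known feature–behavior couplings.

Generates a full recording session — 8-channel two-region LFP,
3-axis accelerometry, bar-press events and a per-video-frame movement
score — driven by a smooth latent behavioral state
z(t), a unit-variance combination of smooth Ornstein–Uhlenbeck
components (2 s correlation time): two partially shared envelope
components z_A, z_B (correlation 0.5) and an independent synchrony
component z_corr, mixed as z = 0.85·(z_A + z_B)/√3 + 0.527·z_corr.

* the high-gamma (80–150 Hz) envelope of one designated channel per
  region is multiplied by exp(0.5·env_gain·z_A) (IL side) or
  exp(0.5·env_gain·z_B) (BLA side);
* the same two channels share a common high-gamma source whose mixing
  fraction rises with z_corr, raising their inter-region band
  correlation without changing either channel's band power;
* accelerometer magnitude is softplus(jerk_gain·z + 1) times a smooth
  carrier, so the computed jerk tracks z;
* bar presses are an inhomogeneous Poisson train with rate
  r0·exp(−press_gain·z) (pressing is suppressed under threat).

Every band oscillator on every channel additionally drifts under its
own independent slow nuisance envelope exp(0.2·w(t)) (OU, 2 s), the
way real band powers wander. This matters for feature attribution:
a band-power *ratio* between channels compounds two independent
nuisance envelopes where the planted band power carries only one, so
informative credit concentrates on the genuinely planted columns.

Splitting the latent into envelope and synchrony components — and
decorrelating the two envelopes — makes every planted pathway carry
information the others do not: a model cannot reach peak performance
from any one channel's band power, so each planted band-power feature
and the inter-region correlation feature must all receive Shapley
credit whenever they carry signal.

Every other channel/band is uncoupled filtered noise over a pink
background, so the informative features are known exactly and recovery
of the planted couplings is testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .behavior import AccelerometryTrace, EventTrain
from .preprocess import DEFAULT_BANDS, Recording

__all__ = ["Gains", "GroundTruth", "generate_session", "worked_fixtures"]

#: per-band oscillator RMS amplitudes (µV-scale), roughly 1/f
_BAND_RMS = {
    "delta": 12.0, "theta": 10.0, "alpha": 8.0, "beta": 6.0,
    "low-gamma": 4.0, "gamma": 3.0, "high-gamma": 3.0,
}
_PINK_RMS = 6.0
_OU_TAU_S = 2.0


@dataclass(frozen=True)
class Gains:
    """Coupling gains between the latent state and the observables.

    All gains at 0 decouple behavior from the LFP entirely.
    """

    env_gain: float = 1.0     # high-gamma envelope modulation depth
    corr_gain: float = 1.0    # inter-region shared-source modulation
    jerk_gain: float = 1.0    # accelerometer magnitude modulation
    press_gain: float = 1.0   # bar-press-rate suppression strength
    press_base_rate: float = 0.2  # presses per second at z = 0

    def __post_init__(self) -> None:
        for name in ("env_gain", "corr_gain", "jerk_gain", "press_gain",
                     "press_base_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def scaled(self, factor: float) -> "Gains":
        return Gains(self.env_gain * factor, self.corr_gain * factor,
                     self.jerk_gain * factor, self.press_gain * factor,
                     self.press_base_rate)


@dataclass
class GroundTruth:
    """What was planted: informative features, gains, latent trace, layout."""

    planted_features: list[str]
    planted_channels: tuple[str, str]
    gains: Gains
    z: np.ndarray          # the behavioral latent driving all couplings
    seed: int
    z_env: np.ndarray | None = None   # (z_a + z_b)/sqrt(3), envelope part
    z_corr: np.ndarray | None = None
    layout: dict = field(default_factory=dict)
    freezing_frames: np.ndarray | None = None


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _ou(rng: np.random.Generator, n: int, fs: float, tau: float) -> np.ndarray:
    """Exact-discretisation Ornstein–Uhlenbeck path, unit stationary variance."""
    a = np.exp(-1.0 / (fs * tau))
    w = rng.standard_normal(n) * np.sqrt(1 - a * a)
    w[0] = rng.standard_normal()  # draw the initial state from stationarity
    return signal.lfilter([1.0], [1.0, -a], w)


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise."""
    sos = signal.butter(3, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise via FFT shaping."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0)
    with np.errstate(divide="ignore"):
        spec *= np.where(f > 0, 1.0 / np.sqrt(f / f[1]), 0.0)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def generate_session(
    seed: int,
    duration_s: float = 600.0,
    fs: float = 1000.0,
    n_channels: int = 8,
    gains: Gains | None = None,
    acc_fs: float | None = None,
) -> tuple[Recording, AccelerometryTrace, EventTrain, GroundTruth]:
    """Generate one fully synthetic session.

    Returns the LFP recording, the accelerometer trace (default emitted
    at 1 kHz; pass ``acc_fs=30000`` for the native-style high rate), the
    bar-press event train, and the ground truth. Same seed, same
    arguments → bit-identical outputs.
    """
    if duration_s < 60:
        raise ValueError("session must be at least 60 s")
    if n_channels < 2 or n_channels % 2:
        raise ValueError("n_channels must be an even number >= 2")
    gains = gains or Gains()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    half = n_channels // 2
    labels = [f"IL{i+1}" for i in range(half)] + [f"BLA{i+1}" for i in range(half)]
    regions = {c: ("IL" if c.startswith("IL") else "BLA") for c in labels}
    planted = (labels[min(1, half - 1)],
               labels[half + min(2, half - 1)])  # one channel per region

    z0 = _ou(rng, n, fs, _OU_TAU_S)
    eta_a = _ou(rng, n, fs, _OU_TAU_S)
    eta_b = _ou(rng, n, fs, _OU_TAU_S)
    z_a = np.sqrt(0.5) * (z0 + eta_a)  # corr(z_a, z_b) = 0.5
    z_b = np.sqrt(0.5) * (z0 + eta_b)
    z_corr = _ou(rng, n, fs, _OU_TAU_S)
    z = 0.85 * (z_a + z_b) / np.sqrt(3.0) + 0.527 * z_corr
    env_a = np.exp(0.5 * gains.env_gain * z_a)
    env_b = np.exp(0.5 * gains.env_gain * z_b)
    rho = 0.15 + 0.7 * _sigmoid(gains.corr_gain * z_corr)
    shared_hg = _band_noise(rng, n, fs, 80.0, min(150.0, 0.45 * fs))

    lfp = np.empty((n_channels, n))
    for ci, ch in enumerate(labels):
        x = _PINK_RMS * _pink_noise(rng, n)
        for name, lo, hi in DEFAULT_BANDS:
            hi = min(hi, 0.45 * fs)
            u = _band_noise(rng, n, fs, lo, hi)
            nuisance = np.exp(0.2 * _ou(rng, n, fs, _OU_TAU_S))
            amp = _BAND_RMS[name] * nuisance
            if name == "high-gamma" and ch in planted:
                env = env_a if ch == planted[0] else env_b
                x += amp * env * (np.sqrt(1 - rho**2) * u + rho * shared_hg)
            else:
                x += amp * u
        lfp[ci] = x
    rec = Recording(lfp, fs, labels, regions)

    # --- accelerometry: magnitude modulated by softplus of the latent state
    a_fs = acc_fs or fs
    factor = int(round(a_fs / fs))
    if factor * fs != a_fs:
        raise ValueError("acc_fs must be an integer multiple of the LFP rate")
    n_acc = n * factor
    z_acc = np.repeat(z, factor)
    carrier = _band_noise(rng, n_acc, a_fs, 2.0, 10.0)
    axis_noise = [0.05 * _band_noise(rng, n_acc, a_fs, 0.5, 20.0)
                  for _ in range(3)]
    mag = _softplus(gains.jerk_gain * z_acc + 1.0) * (1.0 + 0.4 * carrier)
    direction = np.array([2.0, 1.0, 2.0]) / 3.0
    acc = AccelerometryTrace(
        mag * direction[0] + axis_noise[0],
        mag * direction[1] + axis_noise[1],
        mag * direction[2] + axis_noise[2],
        a_fs,
    )

    # --- bar presses: inhomogeneous Poisson, suppressed at high threat
    rate = gains.press_base_rate * np.exp(-gains.press_gain * z)
    p = np.clip(rate / fs, 0.0, 1.0)
    press_bins = rng.random(n) < p
    events = EventTrain(np.flatnonzero(press_bins) / fs)

    # --- freezing-style movement score at 24 fps. The noise is
    # temporally correlated (per-frame pixel-change noise persists over
    # ~1 s), so window averaging cannot remove it: the score is only
    # marginally decodable, as freezing scores are in practice.
    n_frames = int(duration_s * 24)
    z_frames = z[np.minimum((np.arange(n_frames) * fs / 24).astype(int), n - 1)]
    slow_noise = _ou(rng, n_frames, 24.0, 1.0)
    freezing = np.maximum(
        20.0 * _softplus(z_frames) + 25.0 * slow_noise
        + 6.0 * rng.standard_normal(n_frames), 0.0)

    truth = GroundTruth(
        planted_features=[
            f"BP|{planted[0]}|high-gamma||0",
            f"BP|{planted[1]}|high-gamma||0",
            f"BCorr|{planted[0]},{planted[1]}|high-gamma||0",
        ],
        planted_channels=planted,
        gains=gains,
        z=z,
        seed=seed,
        z_env=(z_a + z_b) / np.sqrt(3.0),
        z_corr=z_corr,
        layout={"duration_s": duration_s, "fs": fs, "n_channels": n_channels,
                "labels": labels, "regions": regions},
        freezing_frames=freezing,
    )
    return rec, acc, events, truth


def worked_fixtures() -> dict[str, dict]:
    """Hand-checkable vectors with their expected feature values."""
    return {
        "line_length": {"y": np.array([1.0, 3.0, 2.0]), "expected": 3.0},
        "nonlinear_energy": {"y": np.array([0.0, 2.0, -1.0]), "expected": 4.0,
                             "max": 2.0, "min": -1.0},
        "band_power": {"y": np.array([1.0, -1.0, 1.0, -1.0]), "expected": 1.0},
        "r2": {"y_true": np.array([0.0, 1.0, 2.0]),
               "y_pred": np.array([2.0, 1.0, 0.0]), "expected": -3.0},
    }
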