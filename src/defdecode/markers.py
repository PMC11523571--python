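"""Neuro-marker extraction: 17 feature families per analysis window.

Spectral (band power, relative band power, band-power ratio between
bands), temporal (line length, Hjorth activity/mobility/complexity,
max, min, nonlinear energy, skewness, approximate entropy, sample
entropy) and inter-regional connectivity families (band-power ratio
between channels, coherence, phase-amplitude coupling, phase-locking
value, Pearson correlation, band Pearson correlation).

All families are evaluated on the sliding window grid with cumulative-sum
window statistics (O(1) per window) except the two entropies, which are
O(T^2) template counts compiled with numba.

Degenerate windows (zero power, zero variance, no entropy template
matches) are imputed per family — correlations/synchrony measures to 0,
power ratios to 1, mobility/complexity/sample entropy to the column
median — and counted in the matrix's QC report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .preprocess import BandDecomposition, CrossSpectra, Recording, WindowGrid

__all__ = [
    "FeatureDescriptor",
    "FeatureMatrix",
    "FeatureConfig",
    "band_power_features",
    "line_length",
    "hjorth_parameters",
    "extrema_and_energy",
    "skewness",
    "approximate_entropy",
    "sample_entropy",
    "band_power_ratio_channels",
    "coherence",
    "phase_amplitude_coupling",
    "phase_locking_value",
    "pearson_correlations",
    "extract_feature_matrix",
]

SPECTRAL_FAMILIES = ("BP", "RBP", "BPRB")
TEMPORAL_FAMILIES = ("LL", "HjorthAct", "HjorthMob", "HjorthCom",
                     "Max", "Min", "NE", "Skew", "ApEn", "SampEn")
CONNECTIVITY_FAMILIES = ("BPRC", "Coh", "PAC", "PLV", "Corr", "BCorr")

#: per-family imputation for degenerate windows (None = column median)
_IMPUTE: dict[str, float | None] = {
    "RBP": 0.0, "BPRB": 1.0, "BPRC": 1.0,
    "Corr": 0.0, "BCorr": 0.0, "PLV": 0.0, "Coh": 0.0, "PAC": 0.0,
    "HjorthMob": None, "HjorthCom": None, "SampEn": None, "Skew": 0.0,
}


@dataclass(frozen=True)
class FeatureDescriptor:
    """Structured identity of one feature column."""

    family: str
    channels: tuple[str, ...] = ()
    bands: tuple[str, ...] = ()
    direction: str = ""
    lag_steps: int = 0

    @property
    def name(self) -> str:
        return "|".join([
            self.family,
            ",".join(self.channels),
            ",".join(self.bands),
            self.direction,
            str(self.lag_steps),
        ])


@dataclass
class FeatureMatrix:
    """Windows x named features, with per-column descriptors."""

    values: np.ndarray
    descriptors: list[FeatureDescriptor]
    grid: WindowGrid | None = None
    qc: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.descriptors):
            raise ValueError("values/descriptor count mismatch")

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def subset(self, indices: np.ndarray | list[int]) -> "FeatureMatrix":
        idx = np.asarray(indices)
        return FeatureMatrix(self.values[:, idx],
                             [self.descriptors[i] for i in idx],
                             self.grid, dict(self.qc))

    def descriptor_hash(self) -> str:
        """Stable hash of the ordered descriptor list (config fingerprint)."""
        return hashlib.sha256("\n".join(self.names).encode()).hexdigest()

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, columns=self.names).to_csv(path, index=False)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset("names", data=np.array(self.names, dtype="S"))

    def descriptors_json(self) -> str:
        return json.dumps([d.__dict__ for d in self.descriptors], default=list)


@dataclass
class FeatureConfig:
    """Feature-extraction switches.

    ``symmetric_combinations=False`` (default) emits both orientations of
    the directional families (BPRB, BPRC, PAC), which with 8 channels and
    7 bands yields the full 1296-column matrix; ``True`` restores the
    one-orientation counts (21 band pairs, 7 channel ratios, 6 PAC
    combinations).
    """

    families: tuple[str, ...] = SPECTRAL_FAMILIES + TEMPORAL_FAMILIES + CONNECTIVITY_FAMILIES
    symmetric_combinations: bool = False
    entropy_m: int = 2
    entropy_r_factor: float = 0.2
    pac_phase_bands: tuple[str, ...] = ("theta", "alpha")
    pac_amp_bands: tuple[str, ...] = ("low-gamma", "gamma", "high-gamma")


# ---------------------------------------------------------------- windowing


def _wsum(x: np.ndarray, starts: np.ndarray, length: int) -> np.ndarray:
    """Sum of x over [start, start+length) for each window start."""
    c = np.concatenate([[0], np.cumsum(x, dtype=x.dtype)])
    return c[starts + length] - c[starts]


def _windows_view(x: np.ndarray, grid: WindowGrid) -> np.ndarray:
    """(n_windows, L) view of the window slices (no copy)."""
    sw = np.lib.stride_tricks.sliding_window_view(x, grid.window_length)
    return sw[grid.start_indices]


def _var(x: np.ndarray, starts: np.ndarray, L: int) -> np.ndarray:
    """Per-window sample variance (ddof=1)."""
    s1 = _wsum(x, starts, L)
    s2 = _wsum(x * x, starts, L)
    return np.maximum(s2 - s1 * s1 / L, 0.0) / (L - 1)


# ------------------------------------------------------- scalar-window ops
# These single-window forms mirror the printed formulas; the extractor
# below uses their vectorised equivalents.


def line_length(y: np.ndarray) -> float:
    """LL = sum |y(t+1) - y(t)|."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.diff(y)).sum())


def hjorth_parameters(y: np.ndarray) -> tuple[float, float, float]:
    """(activity, mobility, complexity); derivatives are first differences.

    Mobility/complexity of a zero-variance window are NaN (imputed by the
    matrix-level policy).
    """
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    d = np.diff(y)
    dd = np.diff(d)
    act = y.var(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mob = np.sqrt(d.var(ddof=1) / act) if act > 0 else np.nan
        mob_d = (np.sqrt(dd.var(ddof=1) / d.var(ddof=1))
                 if d.var(ddof=1) > 0 else np.nan)
        com = mob_d / mob if act > 0 and mob and mob > 0 else np.nan
    return float(act), float(mob) if mob == mob else np.nan, com


def extrema_and_energy(y: np.ndarray) -> tuple[float, float, float]:
    """(max, min, mean nonlinear energy y²(t+1) − y(t)y(t+2))."""
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    ne = (y[1:-1] ** 2 - y[:-2] * y[2:]).sum() / (y.size - 2)
    return float(y.max()), float(y.min()), float(ne)


def skewness(y: np.ndarray) -> float:
    """sum (y - mean)^3 / ((T-1) sigma^3), sigma the sample SD (ddof=1)."""
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    s = y.std(ddof=1)
    if s == 0:
        return np.nan
    return float(((y - y.mean()) ** 3).sum() / ((y.size - 1) * s**3))


@njit(cache=True)
def _apen_kernel(y: np.ndarray, r: float, m: int) -> float:
    """ApEn via template counts with Chebyshev distance, d <= r, self-matches kept."""
    T = y.size
    total = 0.0
    for mm in (m, m + 1):
        n_tpl = T - mm + 1
        acc = 0.0
        for p in range(n_tpl):
            cnt = 0
            for q in range(n_tpl):
                d = 0.0
                for v in range(mm):
                    a = abs(y[p + v] - y[q + v])
                    if a > d:
                        d = a
                    if d > r:
                        break
                if d <= r:
                    cnt += 1
            acc += np.log(cnt / n_tpl)
        phi = acc / n_tpl
        if mm == m:
            total = phi
        else:
            total -= phi
    return total


@njit(cache=True)
def _sampen_counts(y: np.ndarray, r: float, m: int) -> tuple[float, float]:
    """(A, B): length-(m+1) and length-m template match counts, d < r, p != q.

    Both counts run p, q over the first T-m templates (Richman-Moorman
    convention), normalised by (T-m-1)(T-m).
    """
    T = y.size
    n = T - m  # templates considered for both lengths
    A = 0
    B = 0
    for p in range(n):
        for q in range(p + 1, n):
            d = 0.0
            for v in range(m):
                a = abs(y[p + v] - y[q + v])
                if a > d:
                    d = a
                if d >= r:
                    break
            if d < r:
                B += 1
                a = abs(y[p + m] - y[q + m])
                if a > d:
                    d = a
                if d < r:
                    A += 1
    norm = (T - m - 1) * (T - m)
    return 2.0 * A / norm, 2.0 * B / norm


def approximate_entropy(y: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Approximate entropy with embedding ``m`` and tolerance ``r``.

    Default tolerance is 0.2 x the window's sample SD. A constant window
    yields 0 (every template matches every other).
    """
    y = np.asarray(y, dtype=np.float64)
    if y.size < 10:
        raise ValueError("window too short for approximate entropy")
    if r is None:
        r = 0.2 * y.std(ddof=1)
    return float(_apen_kernel(y, float(r), m))


def sample_entropy(y: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn = -log(A/B); NaN when no template matches (B or A zero)."""
    y = np.asarray(y, dtype=np.float64)
    if y.size < 10:
        raise ValueError("window too short for sample entropy")
    if r is None:
        r = 0.2 * y.std(ddof=1)
    if r == 0:  # constant window: A = B by convention -> 0
        return 0.0
    A, B = _sampen_counts(y, float(r), m)
    if B == 0 or A == 0:
        return np.nan
    return float(-np.log(A / B))


@njit(cache=True)
def _entropy_window_m2(y: np.ndarray, r: float) -> tuple[float, float, float]:
    """One-pass ApEn (m=2) and SampEn counts for a single window.

    Exploits the symmetry of the template-distance matrix: each (p, q)
    pair with p < q updates both templates' counts, and the length-3
    Chebyshev distance is grown incrementally from the length-2 one.
    Returns (apen, A, B) with A/B already normalised.
    """
    T = y.size
    n2 = T - 1  # length-2 templates (ApEn)
    n3 = T - 2  # length-3 templates (ApEn) and the SampEn range
    cnt2 = np.ones(n2)  # self-matches included
    cnt3 = np.ones(n3)
    A = 0
    B = 0
    for p in range(n2):
        yp0 = y[p]
        yp1 = y[p + 1]
        for q in range(p + 1, n2):
            d0 = abs(yp0 - y[q])
            if d0 > r:
                continue
            d2 = abs(yp1 - y[q + 1])
            if d2 < d0:
                d2 = d0
            if d2 <= r:
                cnt2[p] += 1.0
                cnt2[q] += 1.0
            if q < n3:
                if d2 < r:
                    B += 1
                d3 = abs(y[p + 2] - y[q + 2])
                if d3 < d2:
                    d3 = d2
                if d3 <= r:
                    cnt3[p] += 1.0
                    cnt3[q] += 1.0
                if d3 < r:
                    A += 1
    phi2 = np.mean(np.log(cnt2 / n2))
    phi3 = np.mean(np.log(cnt3 / n3))
    norm = (T - 3) * (T - 2)
    return phi2 - phi3, 2.0 * A / norm, 2.0 * B / norm


@njit(cache=True)
def _entropy_batch(wins: np.ndarray, rs: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    n = wins.shape[0]
    apen = np.empty(n)
    sampen = np.empty(n)
    for i in range(n):
        r = rs[i]
        if r == 0.0:
            apen[i] = 0.0
            sampen[i] = 0.0
            continue
        if m == 2:
            apen[i], A, B = _entropy_window_m2(wins[i], r)
        else:
            apen[i] = _apen_kernel(wins[i], r, m)
            A, B = _sampen_counts(wins[i], r, m)
        if B == 0.0 or A == 0.0:
            sampen[i] = np.nan
        else:
            sampen[i] = -np.log(A / B)
    return apen, sampen


# ----------------------------------------------------------- family slices


def _region_pairs(rec: Recording) -> list[tuple[str, str]]:
    il = rec.channels_in_region("IL")
    bla = rec.channels_in_region("BLA")
    if not il or not bla:
        raise ValueError("connectivity features need channels in both IL and BLA")
    return [(m, n) for m in il for n in bla]


def _band_powers(dec: BandDecomposition, grid: WindowGrid) -> np.ndarray:
    """(n_channels, n_bands, n_windows) mean squared band signal."""
    s, L = grid.start_indices, grid.window_length
    filt = dec.filtered
    out = np.empty((filt.shape[0], filt.shape[1], grid.n_windows))
    for c in range(filt.shape[0]):
        for j in range(filt.shape[1]):
            out[c, j] = _wsum(filt[c, j] ** 2, s, L) / L
    return out


def band_power_features(dec: BandDecomposition, rec: Recording,
                        grid: WindowGrid, symmetric: bool = False
                        ) -> FeatureMatrix:
    """BP, RBP and BPRB for every channel.

    BP_j is the mean squared band-filtered signal; RBP_j normalises by
    the cleaned broadband mean square; BPRB_jk = BP_j / BP_k for ordered
    band pairs (both directions unless ``symmetric``).
    """
    s, L = grid.start_indices, grid.window_length
    bp = _band_powers(dec, grid)
    names = dec.bands.names
    cols, descs = [], []
    for ci, ch in enumerate(rec.channel_labels):
        total = _wsum(rec.samples[ci] ** 2, s, L) / L
        for j, bn in enumerate(names):
            cols.append(bp[ci, j])
            descs.append(FeatureDescriptor("BP", (ch,), (bn,)))
        for j, bn in enumerate(names):
            with np.errstate(divide="ignore", invalid="ignore"):
                cols.append(np.where(total > 0, bp[ci, j] / total, np.nan))
            descs.append(FeatureDescriptor("RBP", (ch,), (bn,)))
        for j, bj in enumerate(names):
            for k, bk in enumerate(names):
                if j == k or (symmetric and j > k):
                    continue
                with np.errstate(divide="ignore", invalid="ignore"):
                    cols.append(np.where(bp[ci, k] > 0, bp[ci, j] / bp[ci, k], np.nan))
                descs.append(FeatureDescriptor("BPRB", (ch,), (bj, bk)))
    return FeatureMatrix(np.column_stack(cols), descs, grid)


def band_power_ratio_channels(dec: BandDecomposition, rec: Recording,
                              grid: WindowGrid, pairs: list[tuple[str, str]],
                              symmetric: bool = False) -> FeatureMatrix:
    """BPRC_jmn = BP_jm / BP_jn per band and inter-region channel pair."""
    bp = _band_powers(dec, grid)
    cols, descs = [], []
    for m, n in pairs:
        im, in_ = rec.channel_index(m), rec.channel_index(n)
        for j, bn in enumerate(dec.bands.names):
            orientations = [((m, n), (im, in_), "IL/BLA")]
            if not symmetric:
                orientations.append(((n, m), (in_, im), "BLA/IL"))
            for chans, (a, b), d in orientations:
                with np.errstate(divide="ignore", invalid="ignore"):
                    cols.append(np.where(bp[b, j] > 0, bp[a, j] / bp[b, j], np.nan))
                descs.append(FeatureDescriptor("BPRC", chans, (bn,), d))
    return FeatureMatrix(np.column_stack(cols), descs, grid)


def _band_bins(freqs: np.ndarray, lo: float, hi: float, fmax: float) -> np.ndarray:
    sel = (freqs >= lo) & (freqs < hi)
    if hi >= fmax:  # last band keeps the top edge
        sel |= freqs == fmax
    return sel


def coherence(cs: CrossSpectra, pairs: list[tuple[str, str]],
              bands) -> FeatureMatrix:
    """Mean magnitude-squared coherency over the bins inside each band.

    Per-bin msc = |G_mn|^2 / (G_mm G_nn); zero auto-spectrum bins are
    skipped; an all-skipped band is NaN (imputed downstream).
    """
    fmax = cs.freqs.max()
    cols, descs = [], []
    for m, n in pairs:
        Gmn = cs.get(m, n)
        Gmm = cs.get(m, m).real
        Gnn = cs.get(n, n).real
        denom = Gmm * Gnn
        with np.errstate(divide="ignore", invalid="ignore"):
            msc = np.where(denom > 0, np.abs(Gmn) ** 2 / denom, np.nan)
        for bn, lo, hi in bands:
            sel = _band_bins(cs.freqs, lo, hi, fmax)
            band_msc = msc[:, sel]
            with np.errstate(invalid="ignore"):
                cols.append(np.nanmean(band_msc, axis=1))
            descs.append(FeatureDescriptor("Coh", (m, n), (bn,)))
    return FeatureMatrix(np.column_stack(cols), descs)


def phase_amplitude_coupling(dec: BandDecomposition, rec: Recording,
                             grid: WindowGrid, pairs: list[tuple[str, str]],
                             phase_bands=("theta", "alpha"),
                             amp_bands=("low-gamma", "gamma", "high-gamma"),
                             symmetric: bool = False) -> FeatureMatrix:
    """PAC = |mean a_amp(t) e^{i theta_phase(t)}| (mean-vector length).

    Both role assignments per inter-region pair (amplitude on IL / phase
    on BLA and the reverse) unless ``symmetric``, in which case only the
    amplitude-on-IL orientation is emitted.
    """
    s, L = grid.start_indices, grid.window_length
    analytic = dec.analytic
    amp = np.abs(analytic)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(amp > 0, analytic / amp, 0.0 + 0.0j)
    cols, descs = [], []
    for m, n in pairs:
        im, in_ = rec.channel_index(m), rec.channel_index(n)
        for pb in phase_bands:
            jp = dec.band_index(pb)
            for ab in amp_bands:
                ja = dec.band_index(ab)
                roles = [((m, n), (im, in_), "amp:IL")]
                if not symmetric:
                    roles.append(((n, m), (in_, im), "amp:BLA"))
                for chans, (ia, ip), d in roles:
                    prod = amp[ia, ja] * unit[ip, jp]
                    cols.append(np.abs(_wsum(prod, s, L)) / L)
                    descs.append(FeatureDescriptor("PAC", chans, (ab, pb), d))
    return FeatureMatrix(np.column_stack(cols), descs, grid)


def phase_locking_value(dec: BandDecomposition, rec: Recording,
                        grid: WindowGrid, pairs: list[tuple[str, str]],
                        ) -> FeatureMatrix:
    """PLV = |mean e^{i(theta_m - theta_n)}| per band and pair."""
    s, L = grid.start_indices, grid.window_length
    analytic = dec.analytic
    amp = np.abs(analytic)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(amp > 0, analytic / amp, 0.0 + 0.0j)
    cols, descs = [], []
    for m, n in pairs:
        im, in_ = rec.channel_index(m), rec.channel_index(n)
        for j, bn in enumerate(dec.bands.names):
            prod = unit[im, j] * np.conj(unit[in_, j])
            cols.append(np.abs(_wsum(prod, s, L)) / L)
            descs.append(FeatureDescriptor("PLV", (m, n), (bn,)))
    return FeatureMatrix(np.column_stack(cols), descs, grid)


def _windowed_corr(x: np.ndarray, y: np.ndarray, s: np.ndarray, L: int
                   ) -> np.ndarray:
    sx, sy = _wsum(x, s, L), _wsum(y, s, L)
    sxx, syy = _wsum(x * x, s, L), _wsum(y * y, s, L)
    sxy = _wsum(x * y, s, L)
    cov = sxy - sx * sy / L
    vx = np.maximum(sxx - sx * sx / L, 0.0)
    vy = np.maximum(syy - sy * sy / L, 0.0)
    denom = np.sqrt(vx * vy)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, np.clip(cov / denom, -1.0, 1.0), np.nan)
    return r


def pearson_correlations(rec: Recording, dec: BandDecomposition,
                         grid: WindowGrid, pairs: list[tuple[str, str]],
                         ) -> FeatureMatrix:
    """Corr on broadband slices; BCorr on band-filtered slices per band."""
    s, L = grid.start_indices, grid.window_length
    cols, descs = [], []
    for m, n in pairs:
        im, in_ = rec.channel_index(m), rec.channel_index(n)
        cols.append(_windowed_corr(rec.samples[im], rec.samples[in_], s, L))
        descs.append(FeatureDescriptor("Corr", (m, n)))
        for j, bn in enumerate(dec.bands.names):
            cols.append(_windowed_corr(dec.filtered[im, j],
                                       dec.filtered[in_, j], s, L))
            descs.append(FeatureDescriptor("BCorr", (m, n), (bn,)))
    return FeatureMatrix(np.column_stack(cols), descs, grid)


def _temporal_features(rec: Recording, grid: WindowGrid,
                       cfg: FeatureConfig) -> FeatureMatrix:
    s, L = grid.start_indices, grid.window_length
    cols, descs = [], []
    for ci, ch in enumerate(rec.channel_labels):
        x = rec.samples[ci]
        d = np.diff(x)
        dd = np.diff(d)
        ll = _wsum(np.abs(d), s, L - 1)
        var_x = _var(x, s, L)
        var_d = _var(d, s, L - 1)
        var_dd = _var(dd, s, L - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            mob = np.where(var_x > 0, np.sqrt(var_d / var_x), np.nan)
            mob_d = np.where(var_d > 0, np.sqrt(var_dd / var_d), np.nan)
            com = np.where((mob > 0) & np.isfinite(mob), mob_d / mob, np.nan)
        wv = _windows_view(x, grid)
        mx, mn = wv.max(axis=1), wv.min(axis=1)
        ne = _wsum(x[1:-1] ** 2 - x[:-2] * x[2:], s, L - 2) / (L - 2)
        s1, s2, s3 = _wsum(x, s, L), _wsum(x * x, s, L), _wsum(x**3, s, L)
        mean = s1 / L
        m3 = s3 - 3 * mean * s2 + 3 * mean**2 * s1 - L * mean**3
        sd = np.sqrt(var_x)
        with np.errstate(divide="ignore", invalid="ignore"):
            skew = np.where(sd > 0, m3 / ((L - 1) * sd**3), np.nan)
        rs = cfg.entropy_r_factor * sd
        apen, sampen = _entropy_batch(np.ascontiguousarray(wv), rs,
                                      cfg.entropy_m)
        for fam, col in [("LL", ll), ("HjorthAct", var_x), ("HjorthMob", mob),
                         ("HjorthCom", com), ("Max", mx), ("Min", mn),
                         ("NE", ne), ("Skew", skew), ("ApEn", apen),
                         ("SampEn", sampen)]:
            cols.append(col)
            descs.append(FeatureDescriptor(fam, (ch,)))
    return FeatureMatrix(np.column_stack(cols), descs, grid)


def _impute(fm: FeatureMatrix) -> None:
    """Apply the degenerate-value policy in place; record QC counts."""
    for k, d in enumerate(fm.descriptors):
        col = fm.values[:, k]
        bad = ~np.isfinite(col)
        if not bad.any():
            continue
        fill = _IMPUTE.get(d.family, 0.0)
        if fill is None:
            finite = col[~bad]
            fill = float(np.median(finite)) if finite.size else 0.0
        col[bad] = fill
        fm.qc[d.family] = fm.qc.get(d.family, 0) + int(bad.sum())


def extract_feature_matrix(rec: Recording, dec: BandDecomposition,
                           cs: CrossSpectra | None, grid: WindowGrid,
                           config: FeatureConfig | None = None
                           ) -> FeatureMatrix:
    """Assemble the full feature matrix in canonical order.

    Channel-wise spectral families first, then channel-wise temporal
    families, then the inter-region connectivity families over all
    IL x BLA channel pairs. The default configuration (8 channels, 4 per
    region, 7 bands, both orientations of the directional families)
    yields 8*56 + 8*10 + 16*48 = 1296 columns.
    """
    cfg = config or FeatureConfig()
    fams = set(cfg.families)
    parts: list[FeatureMatrix] = []
    if fams & set(SPECTRAL_FAMILIES):
        part = band_power_features(dec, rec, grid, cfg.symmetric_combinations)
        keep = [i for i, d in enumerate(part.descriptors) if d.family in fams]
        parts.append(part.subset(keep))
    if fams & set(TEMPORAL_FAMILIES):
        part = _temporal_features(rec, grid, cfg)
        keep = [i for i, d in enumerate(part.descriptors) if d.family in fams]
        parts.append(part.subset(keep))
    if fams & set(CONNECTIVITY_FAMILIES):
        pairs = _region_pairs(rec)
        per_pair: list[FeatureMatrix] = []
        if "BPRC" in fams:
            per_pair.append(band_power_ratio_channels(
                dec, rec, grid, pairs, cfg.symmetric_combinations))
        if "Coh" in fams:
            if cs is None:
                raise ValueError("coherence requested but no cross-spectra given")
            per_pair.append(coherence(cs, pairs, dec.bands))
        if "PAC" in fams:
            per_pair.append(phase_amplitude_coupling(
                dec, rec, grid, pairs, cfg.pac_phase_bands, cfg.pac_amp_bands,
                cfg.symmetric_combinations))
        if "PLV" in fams:
            per_pair.append(phase_locking_value(dec, rec, grid, pairs))
        if fams & {"Corr", "BCorr"}:
            part = pearson_correlations(rec, dec, grid, pairs)
            keep = [i for i, d in enumerate(part.descriptors) if d.family in fams]
            per_pair.append(part.subset(keep))
        # regroup: all families for pair 1, then pair 2, ... (stable order)
        for m, n in pairs:
            for part in per_pair:
                keep = [i for i, d in enumerate(part.descriptors)
                        if set(d.channels) == {m, n}]
                parts.append(part.subset(keep))
    values = np.column_stack([p.values for p in parts])
    descs = [d for p in parts for d in p.descriptors]
    fm = FeatureMatrix(values, descs, grid)
    _impute(fm)
    return fm
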