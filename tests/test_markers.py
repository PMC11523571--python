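"""Marker families: worked examples, degenerate policies, matrix assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import defdecode.markers as mk
from defdecode.markers import (FeatureConfig, approximate_entropy,
                               band_power_features,
                               band_power_ratio_channels, coherence,
                               extract_feature_matrix, extrema_and_energy,
                               hjorth_parameters, line_length,
                               pearson_correlations, phase_amplitude_coupling,
                               phase_locking_value, sample_entropy, skewness)
from defdecode.preprocess import (BandDecomposition, BandSet, Recording,
                                  band_decompose, make_window_grid,
                                  multitaper_csd)

from . import oracles

FS = 1000.0


def _rec(samples, labels, regions):
    return Recording(np.atleast_2d(samples), FS, labels, regions)


def _dec_from_filtered(filtered, bands):
    """BandDecomposition with the given real band signals (phase unused)."""
    return BandDecomposition(filtered.astype(complex), bands, FS)


def _dec_from_polar(amp, phase, bands):
    return BandDecomposition(amp * np.exp(1j * phase), bands, FS)


# ------------------------------------------------------------ scalar families

class TestScalarFamilies:
    def test_line_length_examples(self):
        assert line_length([1.0, 3.0, 2.0]) == 3.0
        assert line_length(np.full(50, 4.2)) == 0.0
        y = np.random.default_rng(0).standard_normal(128)
        assert line_length(y) == pytest.approx(oracles.line_length(y), rel=1e-12)

    def test_hjorth_examples(self):
        act, mob, com = hjorth_parameters(np.full(64, 1.0))
        assert act == 0.0 and np.isnan(mob) and np.isnan(com)
        t = np.arange(4096)
        act, mob, com = hjorth_parameters(np.sin(2 * np.pi * t / 64))
        assert act == pytest.approx(0.5, rel=1e-2)
        assert com == pytest.approx(1.0, rel=1e-2)

    def test_differencing_raises_mobility(self):
        rng = np.random.default_rng(1)
        wins = rng.standard_normal((50, 256))
        mob_noise = np.array([hjorth_parameters(w)[1] for w in wins])
        mob_walk = np.array([hjorth_parameters(np.cumsum(w))[1] for w in wins])
        assert np.all(mob_noise > mob_walk)

    def test_extrema_and_energy_examples(self):
        assert extrema_and_energy([0.0, 2.0, -1.0]) == (2.0, -1.0, 4.0)
        assert extrema_and_energy(np.full(10, 3.0)) == (3.0, 3.0, 0.0)

    def test_nonlinear_energy_of_sinusoid(self):
        w = 0.3
        y = np.sin(w * np.arange(2000))
        _, _, ne = extrema_and_energy(y)
        assert ne == pytest.approx(np.sin(w) ** 2, rel=1e-2)

    def test_skewness_examples(self):
        assert skewness([1.0, 2.0, 3.0, 4.0]) == pytest.approx(0.0, abs=1e-12)
        y = np.array([0.0, 0.0, 0.0, 1.0])
        assert skewness(y) == pytest.approx(oracles.skewness(y), rel=1e-12)
        z = np.random.default_rng(2).standard_normal(64)
        assert skewness(-z) == pytest.approx(-skewness(z), rel=1e-12)

    def test_apen_examples(self):
        assert approximate_entropy(np.full(32, 5.0)) == 0.0
        rng = np.random.default_rng(3)
        periodic = np.tile([0.0, 1.0, -1.0], 40)
        noise = rng.standard_normal(120) * periodic.std()
        assert approximate_entropy(periodic) < approximate_entropy(noise)
        y = rng.standard_normal(15)
        r = 0.2 * y.std(ddof=1)
        assert approximate_entropy(y, 2, r) == pytest.approx(
            oracles.apen(y, r, 2), abs=1e-12)

    def test_sampen_examples(self):
        assert sample_entropy(np.full(32, 1.0)) == 0.0
        rng = np.random.default_rng(4)
        y = rng.standard_normal(15)
        r = 0.8 * y.std(ddof=1)  # generous tolerance so matches exist at T=15
        assert sample_entropy(y, 2, r) == pytest.approx(
            oracles.sampen(y, r, 2), abs=1e-12)
        spread = np.arange(12, dtype=float) ** 2  # no template matches
        assert np.isnan(sample_entropy(spread, 2, 0.01))

    @settings(max_examples=25, deadline=None)
    @given(arrays(np.float64, 32, elements=st.floats(-5, 5)))
    def test_scalar_scale_equivariance(self, y):
        c = 2.5
        assert line_length(c * y) == pytest.approx(c * line_length(y), rel=1e-9,
                                                   abs=1e-12)
        mx1, mn1, ne1 = extrema_and_energy(y)
        mx2, mn2, ne2 = extrema_and_energy(c * y)
        assert mx2 == pytest.approx(c * mx1, abs=1e-12)
        assert mn2 == pytest.approx(c * mn1, abs=1e-12)
        assert ne2 == pytest.approx(c * c * ne1, rel=1e-9, abs=1e-12)


# ----------------------------------------------------------- matrix families

BANDS1 = BandSet((("b0", 4.0, 8.0),))


class TestSpectralSlices:
    def test_bp_mean_square(self):
        filt = np.array([[[1.0, -1.0, 1.0, -1.0]]])  # 1 ch, 1 band, 4 samples
        rec = _rec(np.ones((1, 4)), ["IL1"], {"IL1": "IL"})
        grid = make_window_grid(4, FS, 0.004, 0.004)
        fmx = band_power_features(_dec_from_filtered(filt, BANDS1), rec, grid)
        assert fmx.column("BP|IL1|b0||0")[0] == pytest.approx(1.0)

    def test_bprb_reciprocal_identity(self):
        rng = np.random.default_rng(5)
        bands = BandSet((("b0", 4.0, 8.0), ("b1", 8.0, 13.0)))
        filt = rng.standard_normal((1, 2, 2000))
        rec = _rec(rng.standard_normal((1, 2000)), ["IL1"], {"IL1": "IL"})
        grid = make_window_grid(2000, FS)
        fmx = band_power_features(_dec_from_filtered(filt, bands), rec, grid)
        prod = fmx.column("BPRB|IL1|b0,b1||0") * fmx.column("BPRB|IL1|b1,b0||0")
        assert np.allclose(prod, 1.0, rtol=1e-9)

    def test_rbp_concentrated_in_band(self):
        t = np.arange(5000) / FS
        x = np.sin(2 * np.pi * 10 * t)  # alpha only
        rec = _rec(x, ["IL1"], {"IL1": "IL"})
        dec = band_decompose(rec)
        grid = make_window_grid(5000, FS)
        fmx = band_power_features(dec, rec, grid)
        inner = slice(1, -1)  # first/last windows keep filter transients
        assert np.all(fmx.column("RBP|IL1|alpha||0")[inner] >= 0.9)
        for b in ("delta", "theta", "beta", "low-gamma", "gamma", "high-gamma"):
            assert np.all(fmx.column(f"RBP|IL1|{b}||0")[inner] <= 0.05)


class TestConnectivitySlices:
    def _pair_setup(self, x_m, x_n):
        rec = _rec(np.vstack([x_m, x_n]), ["IL1", "BLA1"],
                   {"IL1": "IL", "BLA1": "BLA"})
        return rec, [("IL1", "BLA1")]

    def test_bprc_identical_and_scaling(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(2000)
        rec, pairs = self._pair_setup(x, x)
        filt = np.stack([x[None], (2.0 * x)[None]])  # channel n at 2x amplitude
        grid = make_window_grid(2000, FS)
        same = band_power_ratio_channels(
            _dec_from_filtered(np.stack([x[None], x[None]]), BANDS1),
            rec, grid, pairs)
        assert np.allclose(same.column("BPRC|IL1,BLA1|b0|IL/BLA|0"), 1.0)
        scaled = band_power_ratio_channels(
            _dec_from_filtered(filt, BANDS1), rec, grid, pairs)
        fwd = scaled.column("BPRC|IL1,BLA1|b0|IL/BLA|0")
        bwd = scaled.column("BPRC|BLA1,IL1|b0|BLA/IL|0")
        assert np.allclose(fwd, 0.25, rtol=1e-9)  # power scales quadratically
        assert np.allclose(fwd * bwd, 1.0, rtol=1e-9)

    def test_plv_examples(self):
        rng = np.random.default_rng(7)
        theta = rng.uniform(-np.pi, np.pi, 1000)
        grid = make_window_grid(1000, FS)
        rec, pairs = self._pair_setup(np.zeros(1000), np.zeros(1000))
        same = _dec_from_polar(np.ones((2, 1, 1000)),
                               np.stack([theta[None], theta[None]]), BANDS1)
        assert phase_locking_value(same, rec, grid, pairs).values[0, 0] == \
            pytest.approx(1.0)
        offset = _dec_from_polar(np.ones((2, 1, 1000)),
                                 np.stack([theta[None], (theta + 0.7)[None]]),
                                 BANDS1)
        assert phase_locking_value(offset, rec, grid, pairs).values[0, 0] == \
            pytest.approx(1.0)

    def test_plv_independent_phases_small(self):
        rng = np.random.default_rng(8)
        grid = make_window_grid(1000, FS)
        rec, pairs = self._pair_setup(np.zeros(1000), np.zeros(1000))
        hits = 0
        for _ in range(50):
            ph = rng.uniform(-np.pi, np.pi, (2, 1, 1000))
            dec = _dec_from_polar(np.ones((2, 1, 1000)), ph, BANDS1)
            v = phase_locking_value(dec, rec, grid, pairs).values[0, 0]
            hits += v < 0.1
        assert hits >= 48  # Rayleigh: resultant of 1000 uniform phases

    def test_pac_examples(self):
        grid = make_window_grid(1000, FS)
        rec, pairs = self._pair_setup(np.zeros(1000), np.zeros(1000))
        bands = BandSet((("theta", 4.0, 8.0), ("low-gamma", 30.0, 50.0)))
        theta = np.linspace(0, 10 * 2 * np.pi, 1000, endpoint=False)
        # constant amplitude, phase covering whole cycles -> no coupling
        amp = np.ones((2, 2, 1000)) * 3.0
        ph = np.tile(theta, (2, 2, 1)).astype(float)
        dec = _dec_from_polar(amp, ph, bands)
        fmx = phase_amplitude_coupling(dec, rec, grid, pairs,
                                       ("theta",), ("low-gamma",))
        assert np.all(fmx.values[0] < 0.05 * 3.0)
        # amplitude 1 + cos(theta) -> mean vector length 1/2
        amp2 = amp.copy()
        amp2[0, 1] = 1.0 + np.cos(theta)
        dec2 = _dec_from_polar(amp2, ph, bands)
        fmx2 = phase_amplitude_coupling(dec2, rec, grid, pairs,
                                        ("theta",), ("low-gamma",))
        v = fmx2.column("PAC|IL1,BLA1|low-gamma,theta|amp:IL|0")[0]
        assert v == pytest.approx(0.5, abs=0.01)
        # zero amplitude -> zero coupling
        amp3 = amp.copy()
        amp3[0, 1] = 0.0
        fmx3 = phase_amplitude_coupling(_dec_from_polar(amp3, ph, bands),
                                        rec, grid, pairs, ("theta",),
                                        ("low-gamma",))
        assert fmx3.column("PAC|IL1,BLA1|low-gamma,theta|amp:IL|0")[0] == 0.0

    def test_corr_examples(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(2000)
        grid = make_window_grid(2000, FS)
        for other, expect in [(x, 1.0), (-x, -1.0)]:
            rec, pairs = self._pair_setup(x, other)
            dec = _dec_from_filtered(np.stack([x[None], other[None]]), BANDS1)
            fmx = pearson_correlations(rec, dec, grid, pairs)
            assert np.allclose(fmx.column("Corr|IL1,BLA1|||0"), expect)
            assert np.allclose(fmx.column("BCorr|IL1,BLA1|b0||0"), expect)

    def test_corr_matches_textbook_formula(self):
        rng = np.random.default_rng(10)
        x, y = rng.standard_normal((2, 1000))
        rec, pairs = self._pair_setup(x, y)
        dec = _dec_from_filtered(np.stack([x[None], y[None]]), BANDS1)
        grid = make_window_grid(1000, FS)
        fmx = pearson_correlations(rec, dec, grid, pairs)
        assert fmx.column("Corr|IL1,BLA1|||0")[0] == pytest.approx(
            oracles.pearson(x, y), abs=1e-12)

    def test_coherence_identical_and_delayed(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(6000)
        rec, pairs = self._pair_setup(x, x)
        grid = make_window_grid(6000, FS)
        cs = multitaper_csd(rec, pairs, grid)
        fmx = coherence(cs, pairs, BandSet())
        assert np.allclose(fmx.values, 1.0, atol=1e-9)
        # 5 ms delay: magnitude-squared coherence ignores the phase ramp
        y = np.roll(x, 5)
        rec2, _ = self._pair_setup(x, y)
        cs2 = multitaper_csd(rec2, pairs, grid)
        fmx2 = coherence(cs2, pairs, BandSet())
        assert np.all(fmx2.column("Coh|IL1,BLA1|high-gamma||0") >= 0.9)

    def test_coherence_independent_noise(self):
        rng = np.random.default_rng(12)
        n = 500 * 1000
        rec, pairs = self._pair_setup(rng.standard_normal(n),
                                      rng.standard_normal(n))
        grid = make_window_grid(n, FS, 1.0, 1.0)
        cs = multitaper_csd(rec, pairs, grid)
        fmx = coherence(cs, pairs, BandSet())
        assert np.all(fmx.values.mean(axis=0) < 0.5)


# -------------------------------------------------------- degenerate windows

class TestImputationPolicy:
    def test_zero_variance_windows_imputed_and_counted(self):
        x = np.zeros(3000)
        x[:1000] = np.sin(2 * np.pi * 10 * np.arange(1000) / FS)
        rec = Recording(np.vstack([x, x]), FS, ["IL1", "BLA1"],
                        {"IL1": "IL", "BLA1": "BLA"})
        dec = band_decompose(rec)
        grid = make_window_grid(3000, FS, 1.0, 1.0)  # 3 disjoint windows
        cs = multitaper_csd(rec, [("IL1", "BLA1")], grid)
        fm = extract_feature_matrix(rec, dec, cs, grid)
        assert np.all(np.isfinite(fm.values))
        # flat windows: ratio families imputed to 1, correlations to 0
        assert fm.column("BPRC|IL1,BLA1|delta|IL/BLA|0")[2] == 1.0
        assert fm.column("Corr|IL1,BLA1|||0")[2] == 0.0
        assert fm.qc.get("Corr", 0) > 0


# ------------------------------------------------------------ full assembly

class TestExtractFeatureMatrix:
    @pytest.fixture(scope="class")
    def tiny_session(self):
        rng = np.random.default_rng(13)
        labels = [f"IL{i}" for i in range(1, 5)] + [f"BLA{i}" for i in range(1, 5)]
        rec = Recording(rng.standard_normal((8, 6000)), FS, labels,
                        {c: c[:2] if c[:2] == "IL" else "BLA" for c in labels})
        dec = band_decompose(rec)
        grid = make_window_grid(6000, FS, 1.0, 1.0)
        pairs = [(m, n) for m in labels[:4] for n in labels[4:]]
        cs = multitaper_csd(rec, pairs, grid)
        return rec, dec, cs, grid

    def test_temporal_only_count(self, tiny_session):
        rec, dec, cs, grid = tiny_session
        rng = np.random.default_rng(14)
        rec2 = Recording(rec.samples[:2], FS, ["IL1", "IL2"],
                         {"IL1": "IL", "IL2": "IL"})
        dec2 = band_decompose(rec2, BandSet((("b0", 4.0, 8.0),)))
        fm = extract_feature_matrix(
            rec2, dec2, None, grid,
            FeatureConfig(families=mk.TEMPORAL_FAMILIES))
        assert fm.n_features == 20

    def test_ordering_and_hash_stable(self, tiny_session):
        rec, dec, cs, grid = tiny_session
        fm1 = extract_feature_matrix(rec, dec, cs, grid)
        fm2 = extract_feature_matrix(rec, dec, cs, grid)
        assert fm1.names == fm2.names
        assert fm1.descriptor_hash() == fm2.descriptor_hash()
        assert np.array_equal(fm1.values, fm2.values)

    def test_missing_region_error(self, tiny_session):
        rec, dec, cs, grid = tiny_session
        il_only = Recording(rec.samples[:4], FS, rec.channel_labels[:4],
                            {c: "IL" for c in rec.channel_labels[:4]})
        dec4 = band_decompose(il_only)
        with pytest.raises(ValueError, match="IL and BLA"):
            extract_feature_matrix(il_only, dec4, None, grid,
                                   FeatureConfig(families=("BPRC",)))
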