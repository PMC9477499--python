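import numpy as np
import pytest

import nremtools as nt
from nremtools import spectral as sp
from nremtools.spectral import PowerSpectrum

FS = 128.0


class TestWelch:
    def test_sinusoid_peak_bin(self):
        t = np.arange(0, 30, 1 / FS)
        ps = sp.welch_psd(np.sin(2 * np.pi * 13 * t), FS)
        assert ps.freqs[np.argmax(ps.power)] == pytest.approx(13.0)

    def test_zero_signal_floor_sentinel(self):
        ps = sp.welch_psd(np.zeros(int(30 * FS)), FS)
        assert np.all(ps.power == 0)
        assert np.all(ps.db == -300.0)

    def test_parseval(self):
        x = np.random.default_rng(1).normal(0, 3.0, int(120 * FS))
        ps = sp.welch_psd(x, FS, fmin=0.0, fmax=FS / 2)
        total = np.trapezoid(ps.power, ps.freqs)
        assert total == pytest.approx(9.0, rel=0.05)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            sp.welch_psd(np.zeros(int(2 * FS)), FS)


class TestWelchZscored:
    def test_scale_invariance(self):
        x = np.random.default_rng(2).standard_normal(int(60 * FS))
        a = sp.welch_psd_zscored(x, FS)
        b = sp.welch_psd_zscored(7 * x, FS)
        np.testing.assert_allclose(a.power, b.power, rtol=1e-12)

    def test_matches_raw_for_standardized_input(self):
        x = np.random.default_rng(3).standard_normal(int(60 * FS))
        x = (x - x.mean()) / x.std()
        np.testing.assert_allclose(sp.welch_psd_zscored(x, FS).power,
                                   sp.welch_psd(x, FS).power, atol=1e-9)

    def test_band_shares_preserved(self):
        t = np.arange(0, 60, 1 / FS)
        x = np.sin(2 * np.pi * 13 * t) + 0.5 * np.sin(2 * np.pi * 3 * t)
        raw = sp.welch_psd(x, FS)
        z = sp.welch_psd_zscored(x, FS)
        share = lambda ps, lo, hi: (ps.power[(ps.freqs >= lo) & (ps.freqs <= hi)].sum()
                                    / ps.power.sum())
        assert share(raw, 10, 16) == pytest.approx(share(z, 10, 16), rel=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            sp.welch_psd_zscored(np.ones(int(60 * FS)), FS)


class TestMultitaper:
    def test_column_count(self):
        x = np.zeros(int(300 * FS))
        _, times, S = sp.multitaper_spectrogram(x + 1e-6, FS)
        assert S.shape[1] == 28

    def test_stationary_sinusoid_peak_every_column(self):
        t = np.arange(0, 120, 1 / FS)
        f, _, S = sp.multitaper_spectrogram(np.sin(2 * np.pi * 13 * t), FS)
        assert np.all(f[S.argmax(axis=0)] == pytest.approx(13.0, abs=0.5))

    def test_marginal_agrees_with_welch_on_noise(self):
        x = np.random.default_rng(4).standard_normal(int(300 * FS))
        f, _, S = sp.multitaper_spectrogram(x, FS)
        w = sp.welch_psd(x, FS)
        mt_db = 10 * np.log10(np.interp(w.freqs, f, S.mean(axis=1)))
        sel = (w.freqs >= 1) & (w.freqs <= 20)
        assert np.abs(mt_db[sel] - w.db[sel]).max() < 1.0

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            sp.multitaper_spectrogram(np.zeros(int(10 * FS)), FS)


class TestIrasa:
    def test_residual_identity(self, quiet_sim):
        x = quiet_sim[0].samples[0]
        raw = sp.welch_psd(x, FS)
        frac, osc = sp.irasa(x, FS)
        np.testing.assert_allclose(frac.power + osc.power, raw.power,
                                   rtol=1e-12)

    def test_oscillation_recovered(self, quiet_sim):
        x = quiet_sim[0].samples[0]
        x13 = x + 20 * np.sin(2 * np.pi * 13 * np.arange(x.size) / FS)
        _, osc = sp.irasa(x13, FS)
        assert osc.freqs[np.argmax(osc.power)] == pytest.approx(13.0, abs=0.25)

    def test_pure_fractal_leaves_small_residual(self, n2_hypnogram):
        """Seed-averaged oscillatory residual of shaped 1/f^2 noise stays
        below 10% of the fractal estimate at every bin in 2-20 Hz."""
        oscs, fras = [], []
        for seed in range(10):
            p = nt.SimParams(duration_s=300, seed=seed, sw_density_per_min=0,
                             sp_density_per_min=0, aperiodic_slope_true=2.0,
                             stage_sequence=n2_hypnogram(10))
            x = nt.simulate_recording(p)[0].samples[0]
            frac, osc = sp.irasa(x, FS)
            oscs.append(osc.power)
            fras.append(frac.power)
        om, fm = np.mean(oscs, axis=0), np.mean(fras, axis=0)
        sel = (frac.freqs >= 2) & (frac.freqs <= 20)
        assert np.max(np.abs(om[sel]) / fm[sel]) < 0.10

    def test_empty_hset_rejected(self, quiet_sim):
        with pytest.raises(ValueError):
            sp.irasa(quiet_sim[0].samples[0], FS, hset=[])


class TestAperiodicFit:
    def test_exact_power_law(self):
        f = np.arange(0.25, 20.01, 0.25)
        ps = PowerSpectrum(f, np.exp(2.0) * f ** -1.5, kind="fractal")
        fit = sp.fit_aperiodic(ps)
        assert fit.slope == pytest.approx(1.5, abs=1e-9)
        assert fit.intercept == pytest.approx(2.0, abs=1e-9)
        assert fit.rmse < 1e-12

    def test_flat_spectrum_zero_slope(self):
        f = np.arange(1, 20.01, 0.25)
        fit = sp.fit_aperiodic(PowerSpectrum(f, np.full(f.size, 5.0)))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_bins_dropped_then_error(self):
        f = np.arange(1, 20.01, 0.25)
        p = np.full(f.size, -1.0)
        p[:4] = 1.0
        with pytest.raises(ValueError, match="at least 5"):
            sp.fit_aperiodic(PowerSpectrum(f, p))


class TestSigmaPeakAndBandPower:
    def test_injected_peak(self):
        f = np.arange(0.25, 20.01, 0.25)
        p = np.zeros(f.size)
        p[f == 11.5] = 1.0
        peak = sp.peak_sigma_frequency(PowerSpectrum(f, p, kind="oscillatory"))
        assert peak.freq_hz == 11.5 and not peak.fallback

    def test_fallback_flag(self):
        f = np.arange(0.25, 20.01, 0.25)
        peak = sp.peak_sigma_frequency(
            PowerSpectrum(f, -np.ones(f.size), kind="oscillatory"))
        assert peak.freq_hz == 13.0 and peak.fallback

    def test_band_power_constant_and_single_bin(self):
        f = np.arange(0.25, 20.01, 0.25)
        ps = PowerSpectrum(f, np.full(f.size, 10.0))
        assert sp.band_power(ps, (1, 4)) == pytest.approx(10 * np.log10(10))
        one = sp.band_power(ps, (2.0, 2.0))
        assert one == pytest.approx(ps.db[f == 2.0][0])

    def test_band_power_brute_force(self):
        rng = np.random.default_rng(5)
        f = np.arange(0.25, 20.01, 0.25)
        p = rng.uniform(0.5, 2.0, f.size)
        ps = PowerSpectrum(f, p)
        sel = (f >= 10) & (f <= 16)
        assert sp.band_power(ps, (10, 16)) == pytest.approx(
            np.mean(10 * np.log10(p[sel])))

    def test_empty_band_rejected(self):
        f = np.arange(1, 20.01, 0.25)
        with pytest.raises(ValueError):
            sp.band_power(PowerSpectrum(f, np.ones(f.size)), (0.3, 0.4))


class TestScaleCovariance:
    def test_db_shift_and_zscore_invariance(self):
        x = np.random.default_rng(6).standard_normal(int(120 * FS))
        k = 7.0
        raw_a, raw_b = sp.welch_psd(x, FS), sp.welch_psd(k * x, FS)
        np.testing.assert_allclose(raw_b.db - raw_a.db,
                                   20 * np.log10(k), atol=1e-6)
        za, zb = sp.welch_psd_zscored(x, FS), sp.welch_psd_zscored(k * x, FS)
        np.testing.assert_allclose(za.db, zb.db, atol=1e-6)


class TestSpectralSummary:
    def test_missing_stage_flagged_and_identical_channels_agree(self, n2_hypnogram):
        p = nt.SimParams(duration_s=300, seed=8, stage_sequence=n2_hypnogram(10))
        rec, h, _ = nt.simulate_recording(p)
        two = nt.Recording(np.vstack([rec.samples[0], rec.samples[0]]), FS,
                           ["a", "b"])
        from nremtools import preprocess as pp
        mask = pp.reject_artifacts(two, h)
        rows = sp.spectral_summary(two, h, mask)
        import pandas as pd
        df = pd.DataFrame(rows)
        rem = df.query("stage == 'REM'")["value"]
        assert rem.isna().all()          # no REM epochs in the hypnogram
        a = df.query("channel == 'a'").set_index(["stage", "measure"])["value"]
        b = df.query("channel == 'b'").set_index(["stage", "measure"])["value"]
        pd.testing.assert_series_equal(a, b, check_names=False)

    def test_slope_recovered_from_generative_background(self, quiet_sim):
        rec, h, _ = quiet_sim
        frac, _ = sp.irasa(rec.samples[0], FS)
        fit = sp.fit_aperiodic(frac)
        assert fit.slope == pytest.approx(1.5, abs=0.15)
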