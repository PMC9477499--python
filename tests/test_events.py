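import numpy as np
import pytest

import nremtools as nt
from nremtools import events as ev
from nremtools.spectral import welch_psd

FS = 128.0


class TestWaveletMagnitude:
    def test_steady_response_on_center_frequency(self):
        t = np.arange(0, 20, 1 / FS)
        mag = ev.cfbs_magnitude(np.sin(2 * np.pi * 13 * t), FS, 13.0)
        core = mag[int(2 * FS):-int(2 * FS)]
        assert core.std() / core.mean() < 0.05

    def test_bandpass_selectivity(self):
        """The order-2, bandwidth-2 B-spline wavelet has a triangular spectral
        profile of half-width ~fc, so a tone 4 Hz off-center is attenuated to
        roughly (1 - 4/13) of the on-center response."""
        t = np.arange(0, 20, 1 / FS)
        on = ev.cfbs_magnitude(np.sin(2 * np.pi * 13 * t), FS, 13.0)
        off = ev.cfbs_magnitude(np.sin(2 * np.pi * 17 * t), FS, 13.0)
        sl = slice(int(2 * FS), -int(2 * FS))
        ratio = on[sl].mean() / off[sl].mean()
        assert 1.3 < ratio < 1.7
        far = ev.cfbs_magnitude(np.sin(2 * np.pi * 2 * t), FS, 13.0)
        assert on[sl].mean() / far[sl].mean() > 5

    def test_zero_signal(self):
        mag = ev.cfbs_magnitude(np.zeros(int(10 * FS)), FS, 13.0)
        assert np.allclose(mag, 0)

    def test_center_out_of_band(self):
        with pytest.raises(ValueError):
            ev.cfbs_magnitude(np.zeros(int(10 * FS)), FS, 8.0)


class TestDetectSpindles:
    def test_zero_signal_empty(self):
        x = np.zeros(int(60 * FS))
        assert ev.detect_spindles(x, FS, np.arange(x.size)) == []

    def test_close_bursts_merge(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1.0, int(120 * FS))
        t = np.arange(x.size) / FS

        def burst(t0, dur):
            env = np.clip(1 - np.abs((t - t0 - dur / 2) / (dur / 2)), 0, 1)
            return 20 * env * np.sin(2 * np.pi * 13 * t)

        x = x + burst(60.0, 0.7) + burst(61.0, 0.8)   # 0.3 s gap
        evs = ev.detect_spindles(x, FS, np.arange(x.size),
                                 nt.DetectorConfig(sp_center_hz=13))
        near = [e for e in evs if 59 < e.start_s < 63]
        assert len(near) == 1
        assert near[0].duration_s == pytest.approx(1.8, abs=0.4)

    def test_recovery_on_standard_fixture(self, n2_hypnogram, event_matcher):
        p = nt.SimParams(duration_s=300, seed=2, background_rms_uV=5.0,
                         sp_density_per_min=2, sp_amp_uV=15.0, sp_freq_hz=13.0,
                         sp_dur_lo_s=1.0, sp_dur_hi_s=1.0,
                         sw_density_per_min=0,
                         stage_sequence=n2_hypnogram(10))
        rec, h, truth = nt.simulate_recording(p)
        evs = ev.detect_spindles(rec.samples[0], FS, np.arange(rec.n_samples),
                                 nt.DetectorConfig(sp_center_hz=13))
        tp, fp = event_matcher([e.peak_s for e in evs],
                               [e[2] for e in truth.sp_events], 0.25)
        assert tp / len(truth.sp_events) >= 0.9
        assert fp == 0

    def test_events_respect_duration_and_disjointness(self, standard_sim):
        rec, _, _ = standard_sim
        evs = ev.detect_spindles(rec.samples[0], FS, np.arange(rec.n_samples),
                                 nt.DetectorConfig(sp_center_hz=13))
        for e in evs:
            assert 0.5 <= e.duration_s <= 3.0
            assert e.start_s < e.peak_s < e.end_s
        for a, b in zip(evs, evs[1:]):
            assert b.start_s >= a.end_s


@pytest.fixture(scope="module")
def baseline():
    x = np.random.default_rng(0).standard_normal(int(300 * FS))
    return x, welch_psd(x, FS, fmin=0.25, fmax=30.0)


class TestSpindleQuality:

    def test_sigma_burst_passes(self, baseline):
        t = np.arange(0, 1, 1 / FS)
        assert ev.spindle_quality(10 * np.sin(2 * np.pi * 13 * t), FS,
                                  baseline[1])

    def test_slow_wave_fails(self, baseline):
        t = np.arange(0, 1, 1 / FS)
        assert not ev.spindle_quality(10 * np.sin(2 * np.pi * 2 * t), FS,
                                      baseline[1])

    def test_featureless_noise_is_a_coin_flip(self, baseline):
        """Windows drawn from the baseline's own noise pass roughly half the
        time: all band increases hover near 1, and by symmetry the sigma
        increase beats the mean of the other three ~50% of draws."""
        x, base = baseline
        passes = sum(ev.spindle_quality(x[k * 128:(k + 1) * 128], FS, base)
                     for k in range(100))
        assert 20 <= passes <= 65


class TestSpindleFeatures:
    @pytest.mark.parametrize("f0", [11.0, 13.0])
    def test_sinusoid_frequency_and_amplitude(self, f0):
        t = np.arange(0, 2, 1 / FS)
        seg = 12 * np.sin(2 * np.pi * f0 * t)
        amp, freq = ev.spindle_features(seg, FS)
        assert freq == pytest.approx(f0, abs=0.05)
        assert amp == pytest.approx(24, rel=0.05)

    def test_single_peak_frequency_missing(self):
        t = np.arange(0, 1, 1 / FS)
        seg = np.exp(-((t - 0.5) ** 2) / 0.01)     # one bump
        _, freq = ev.spindle_features(seg, FS)
        assert np.isnan(freq)


def sw_fixture(seed=0, n_events=49, amp=150.0, dur=1.0, total_s=600):
    """Light-tailed delta background (amplitude-modulated 1.1 Hz carrier plus
    a little white noise) carrying injected half-sine down-states."""
    rng = np.random.default_rng(seed)
    n = int(total_s * FS)
    t = np.arange(n) / FS
    am = 1 + 0.3 * np.sin(2 * np.pi * 0.05 * t + 1.0)
    x = 7 * am * np.sin(2 * np.pi * 1.1 * t + rng.uniform(0, 2 * np.pi))
    x = x + 1.5 * rng.standard_normal(n)
    troughs = []
    positions = np.linspace(10 * FS, n - 12 * FS, n_events).astype(int)
    for c in positions:
        k = nt.make_sw_kernel(amp, dur, FS)
        x[c:c + k.size] += k
        troughs.append((c + int(np.argmin(k))) / FS)
    return x, troughs


class TestDetectSlowWaves:
    def test_pure_sinusoid_yields_nothing(self):
        t = np.arange(0, 120, 1 / FS)
        x = 80 * np.sin(2 * np.pi * 1.0 * t)
        assert ev.detect_slow_waves(x, FS, np.arange(x.size)) == []

    def test_injected_half_sines_recovered(self, event_matcher):
        """Each injected down-state is found at its trough; the reported
        amplitude matches the band-passed waveform (the 0.25-4 Hz filter
        removes the half-sine's DC pedestal, so the oracle is the filtered
        kernel's minimum, about -103 µV for a 150 µV, 1-s half-sine).  The
        filter's rebound ripple may add at most one marginal detection."""
        k = nt.make_sw_kernel(150, 1.0, FS)
        padded = np.zeros(int(60 * FS))
        padded[int(30 * FS):int(30 * FS) + k.size] = k
        amp_oracle = ev.sw_bandpass(padded, FS).min()
        x, troughs = sw_fixture(seed=1, n_events=3)
        sws = ev.detect_slow_waves(x, FS, np.arange(x.size))
        tp, fp = event_matcher([s.trough_s for s in sws], troughs, 0.05)
        assert tp == 3
        assert fp <= 1
        matched = [s for s in sws
                   if any(abs(s.trough_s - t) <= 0.05 for t in troughs)]
        for s in matched:
            assert s.amplitude_uV == pytest.approx(amp_oracle, rel=0.15)
            assert s.amplitude_uV < 0
            assert s.start_s < s.trough_s < s.end_s

    def test_overlong_half_waves_rejected_by_duration(self):
        """A large 0.2 Hz component creates ~2.5-s filtered half-waves that
        clear the amplitude threshold but fail the 2-s duration cap."""
        rng = np.random.default_rng(2)
        t = np.arange(int(600 * FS)) / FS
        x = 40 * np.sin(2 * np.pi * 0.2 * t) + 1.0 * rng.standard_normal(t.size)
        sws = ev.detect_slow_waves(x, FS, np.arange(x.size))
        assert sws == []


class TestEventDensity:
    def test_rate(self):
        assert ev.event_density([None] * 30, 60.0) == 0.5

    def test_empty(self):
        assert ev.event_density([], 10.0) == 0.0

    def test_zero_time_rejected(self):
        with pytest.raises(ValueError):
            ev.event_density([], 0.0)

    def test_density_consistent_under_epoch_exclusion(self, n2_hypnogram):
        """Dropping an epoch from the analyzed set removes its events from
        the numerator and its minutes from the denominator."""
        p = nt.SimParams(duration_s=600, seed=4, stage_sequence=n2_hypnogram(20))
        rec, h, _ = nt.simulate_recording(p)
        spe = int(30 * FS)
        idx_all = np.arange(rec.n_samples)
        idx_drop = idx_all[(idx_all < 10 * spe) | (idx_all >= 11 * spe)]
        all_evs = ev.detect_slow_waves(rec.samples[0], FS, idx_all)
        sub_evs = ev.detect_slow_waves(rec.samples[0], FS, idx_drop)
        assert all(not (300 <= s.trough_s < 330) for s in sub_evs)
        d_all = ev.event_density(all_evs, 10.0)
        d_sub = ev.event_density(sub_evs, 9.5)
        assert d_sub == pytest.approx(d_all, rel=0.35)
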