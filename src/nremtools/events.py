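"""Sleep-spindle and slow-wave detection on surviving N2+N3 data.

Spindles: magnitude of the continuous wavelet transform at an individualized
center frequency (complex frequency B-spline wavelet, order 2, bandwidth 2),
smoothed with a 0.1-s moving average.  Candidate cores cross 3× the median
magnitude (median over the whole analyzed signal) and are extended outward to
the flanking 1.5×-median crossings; 0.5–3 s duration, <0.5 s gaps merged
unless the merged span exceeds 3 s, plus a spectral quality metric (the
sigma-band power increase over the whole-signal baseline must exceed the mean
increase in the delta, theta and beta bands).

Slow waves: negative half-waves of the 0.25–4 Hz filtered signal, kept when
the trough exceeds twice the median absolute trough over all negative
half-waves and the half-wave lasts 0.5–2 s.

Both detectors use median-relative thresholds and are therefore invariant to
amplitude rescaling of a channel.  Detection runs per contiguous segment of
the analyzed signal; candidates touching a segment edge are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal

from .io import logger

SIGMA_BAND = (10.0, 16.0)
QUALITY_BANDS = {"delta": (1.0, 4.0), "theta": (4.0, 8.0),
                 "sigma": (10.0, 16.0), "beta": (16.0, 25.0)}


@dataclass
class DetectorConfig:
    sp_center_hz: float = 13.0
    sp_main_mult: float = 3.0
    sp_secondary_mult: float = 1.5
    sp_min_s: float = 0.5
    sp_max_s: float = 3.0
    sp_merge_gap_s: float = 0.5
    smooth_s: float = 0.1
    sw_band_hz: tuple[float, float] = (0.25, 4.0)
    sw_amp_mult: float = 2.0
    sw_min_s: float = 0.5
    sw_max_s: float = 2.0
    sigma_fir_order: int = 960          # least-squares linear-phase FIR
    sigma_fir_transition_hz: float = 0.5
    mrl_shuffle_domain: str = "window"  # "window" (±1.5 s) or "extent"


@dataclass
class SpindleEvent:
    channel: str
    start_s: float
    peak_s: float
    end_s: float
    amplitude_uV: float
    frequency_hz: float     # NaN when fewer than 2 positive peaks

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SlowWaveEvent:
    channel: str
    start_s: float          # positive-to-negative zero crossing
    trough_s: float
    end_s: float            # negative-to-positive zero crossing
    amplitude_uV: float     # signed, negative (peak negative deflection)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


# ---------------------------------------------------------------------------
# Segments of the analyzed signal
# ---------------------------------------------------------------------------

def contiguous_segments(indices: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) runs of consecutive sample indices."""
    idx = np.asarray(indices)
    if idx.size == 0:
        return []
    brk = np.flatnonzero(np.diff(idx) != 1)
    starts = np.r_[0, brk + 1]
    stops = np.r_[brk, idx.size - 1]
    return [(int(idx[a]), int(idx[b]) + 1) for a, b in zip(starts, stops)]


# ---------------------------------------------------------------------------
# Wavelet magnitude
# ---------------------------------------------------------------------------

_WAVELET = "fbsp2-2-1.0"


def _cfbs_mag_raw(x: np.ndarray, fs: float, center_hz: float) -> np.ndarray:
    w = pywt.ContinuousWavelet(_WAVELET)
    scale = pywt.frequency2scale(w, center_hz / fs)
    coef, _ = pywt.cwt(x, [scale], w, method="fft")
    return np.abs(coef[0])


def cfbs_magnitude(x: np.ndarray, fs: float, center_hz: float,
                   smooth_s: float = 0.1) -> np.ndarray:
    """Smoothed CWT magnitude at ``center_hz`` (fbsp order 2, bandwidth 2)."""
    if not SIGMA_BAND[0] <= center_hz <= SIGMA_BAND[1]:
        raise ValueError(f"center frequency {center_hz} Hz outside "
                         f"{SIGMA_BAND}")
    mag = _cfbs_mag_raw(np.asarray(x, dtype=float), fs, center_hz)
    n = max(1, int(round(smooth_s * fs)) | 1)
    return np.convolve(mag, np.ones(n) / n, mode="same")


# ---------------------------------------------------------------------------
# FIR helpers
# ---------------------------------------------------------------------------

def sigma_fir_filter(x: np.ndarray, fs: float, cfg: DetectorConfig | None = None
                     ) -> np.ndarray:
    """Zero-phase sigma (10–16 Hz) least-squares FIR band-pass."""
    cfg = cfg or DetectorConfig()
    taps = _sigma_taps(fs, cfg)
    return signal.fftconvolve(x, taps, mode="same")


_TAP_CACHE: dict = {}


def _sigma_taps(fs: float, cfg: DetectorConfig) -> np.ndarray:
    key = ("sigma", fs, cfg.sigma_fir_order, cfg.sigma_fir_transition_hz)
    if key not in _TAP_CACHE:
        tw = cfg.sigma_fir_transition_hz
        lo, hi = SIGMA_BAND
        _TAP_CACHE[key] = signal.firls(
            cfg.sigma_fir_order + 1,
            [0, lo - tw, lo, hi, hi + tw, fs / 2],
            [0, 0, 1, 1, 0, 0], fs=fs)
    return _TAP_CACHE[key]


def sw_bandpass(x: np.ndarray, fs: float,
                band: tuple[float, float] = (0.25, 4.0)) -> np.ndarray:
    """Zero-phase Hamming-windowed-sinc FIR band-pass (slow-wave band).

    The nominal length (transition width 0.25 Hz) is shortened for short
    segments so the kernel never exceeds the data.
    """
    x = np.asarray(x, dtype=float)
    nominal = int(3.3 * fs / 0.25) | 1
    numtaps = min(nominal, (x.size - 1) | 1)
    numtaps = max(numtaps, 33)
    key = ("sw", fs, band, numtaps)
    if key not in _TAP_CACHE:
        _TAP_CACHE[key] = signal.firwin(numtaps, band, pass_zero=False,
                                        window="hamming", fs=fs)
    return signal.fftconvolve(x, _TAP_CACHE[key], mode="same")


# ---------------------------------------------------------------------------
# Spindles
# ---------------------------------------------------------------------------

def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.r_[False, mask, False]
    d = np.diff(padded.astype(int))
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


def spindle_quality(ev_samples: np.ndarray, fs: float,
                    baseline_psd) -> bool:
    """Quality metric: sigma-band power increase over the whole-signal
    baseline must exceed the mean increase of delta, theta and beta."""
    f, p = signal.periodogram(ev_samples, fs=fs, window="hann", detrend=False)
    increases = {}
    for name, (lo, hi) in QUALITY_BANDS.items():
        ev = p[(f >= lo) & (f <= hi)].mean()
        bsel = (baseline_psd.freqs >= lo) & (baseline_psd.freqs <= hi)
        base = baseline_psd.power[bsel].mean() if np.any(bsel) else 0.0
        increases[name] = ev / base if base > 0 else np.nan
    others = [increases[b] for b in ("delta", "theta", "beta")
              if np.isfinite(increases[b])]
    if not others or not np.isfinite(increases["sigma"]):
        return False
    return increases["sigma"] > float(np.mean(others))


def spindle_features(seg_filtered: np.ndarray, fs: float
                     ) -> tuple[float, float]:
    """(amplitude, frequency) of one event from the sigma-filtered signal:
    the largest adjacent peak-to-trough excursion, and the reciprocal of the
    mean inter-positive-peak interval (NaN below 2 positive peaks)."""
    peaks, _ = signal.find_peaks(seg_filtered)
    troughs, _ = signal.find_peaks(-seg_filtered)
    ext = np.sort(np.r_[peaks, troughs])
    amp = float(np.max(np.abs(np.diff(seg_filtered[ext])))) if ext.size >= 2 \
        else float(np.ptp(seg_filtered))
    pos = peaks[seg_filtered[peaks] > 0]
    freq = float(1.0 / (np.mean(np.diff(pos)) / fs)) if pos.size >= 2 else np.nan
    return amp, freq


def detect_spindles(x_full: np.ndarray, fs: float, indices: np.ndarray,
                    cfg: DetectorConfig | None = None,
                    baseline_psd=None) -> list[SpindleEvent]:
    """Detect spindles on the surviving N2+N3 samples of one channel.

    ``x_full`` is the whole-record trace; ``indices`` the analyzed sample
    indices (events are reported in record time).
    """
    from .spectral import welch_psd

    cfg = cfg or DetectorConfig()
    segs = contiguous_segments(indices)
    if not segs:
        return []
    mags = {s: cfbs_magnitude(x_full[s[0]:s[1]], fs, cfg.sp_center_hz,
                              cfg.smooth_s) for s in segs}
    med = float(np.median(np.concatenate(list(mags.values()))))
    if med == 0:
        logger.warning("zero median wavelet magnitude; no spindles detectable")
        return []
    main, sec = cfg.sp_main_mult * med, cfg.sp_secondary_mult * med
    if baseline_psd is None:
        analyzed = np.concatenate([x_full[a:b] for a, b in segs])
        baseline_psd = welch_psd(analyzed, fs, fmin=0.25, fmax=30.0)

    events: list[SpindleEvent] = []
    for (a, b) in segs:
        mag = mags[(a, b)]
        cand: list[tuple[int, int]] = []
        for s0, s1 in _runs_above(mag > main):
            lo = s0
            while lo > 0 and mag[lo - 1] > sec:
                lo -= 1
            hi = s1
            while hi < mag.size and mag[hi] > sec:
                hi += 1
            if lo == 0 or hi == mag.size:
                continue        # touches a segment edge: duration unverifiable
            if cand and lo <= cand[-1][1]:
                cand[-1] = (cand[-1][0], max(cand[-1][1], hi))
            else:
                cand.append((lo, hi))
        # duration rule, then merge near events unless the union is too long
        cand = [(lo, hi) for lo, hi in cand
                if cfg.sp_min_s <= (hi - lo) / fs <= cfg.sp_max_s]
        merged: list[tuple[int, int]] = []
        for lo, hi in cand:
            if merged and (lo - merged[-1][1]) / fs < cfg.sp_merge_gap_s:
                union = (merged[-1][0], hi)
                if (union[1] - union[0]) / fs <= cfg.sp_max_s:
                    merged[-1] = union
                    continue
            merged.append((lo, hi))
        seg_sigma = sigma_fir_filter(x_full[a:b], fs, cfg)
        for lo, hi in merged:
            ev = x_full[a + lo:a + hi]
            if not spindle_quality(ev, fs, baseline_psd):
                continue
            peak = lo + int(np.argmax(mag[lo:hi]))
            amp, freq = spindle_features(seg_sigma[lo:hi], fs)
            events.append(SpindleEvent(
                channel="", start_s=(a + lo) / fs, peak_s=(a + peak) / fs,
                end_s=(a + hi) / fs, amplitude_uV=amp, frequency_hz=freq))
    return events


# ---------------------------------------------------------------------------
# Slow waves
# ---------------------------------------------------------------------------

def detect_slow_waves(x_full: np.ndarray, fs: float, indices: np.ndarray,
                      cfg: DetectorConfig | None = None
                      ) -> list[SlowWaveEvent]:
    """Negative half-wave slow-wave detector on the surviving N2+N3 samples."""
    cfg = cfg or DetectorConfig()
    segs = contiguous_segments(indices)
    halfwaves: list[tuple[int, int, int, float]] = []  # start, trough, end, amp
    for (a, b) in segs:
        xf = sw_bandpass(x_full[a:b], fs, cfg.sw_band_hz)
        pos = xf > 0
        desc = np.flatnonzero(pos[:-1] & ~pos[1:])      # P->N at i+1
        asc = np.flatnonzero(~pos[:-1] & pos[1:])
        for d in desc:
            k = np.searchsorted(asc, d)
            if k >= asc.size:
                break                                   # touches segment edge
            e = int(asc[k])
            seg = xf[d + 1:e + 1]
            if seg.size == 0:
                continue
            tloc = d + 1 + int(np.argmin(seg))
            halfwaves.append((a + d + 1, a + tloc, a + e, float(xf[tloc])))
    if not halfwaves:
        return []
    amps = np.array([abs(hw[3]) for hw in halfwaves])
    med = float(np.median(amps))
    out = []
    for (s, t, e, amp), a_ in zip(halfwaves, amps):
        dur = (e - s) / fs
        if a_ > cfg.sw_amp_mult * med and cfg.sw_min_s <= dur <= cfg.sw_max_s:
            out.append(SlowWaveEvent(channel="", start_s=s / fs, trough_s=t / fs,
                                     end_s=e / fs, amplitude_uV=amp))
    return out


def event_density(events: list, analyzed_minutes: float) -> float:
    """Events per minute of analyzed (surviving N2+N3) time."""
    if analyzed_minutes <= 0:
        raise ValueError("analyzed time must be positive")
    return len(events) / analyzed_minutes
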